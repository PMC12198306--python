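"""Gain/loss counting for a binary character on a rooted species tree.

Used to weigh evolutionary scenarios for a trait such as cassette-exon
skipping: the unconstrained minimum number of state changes (small
parsimony, Fitch/Sankoff with unit symmetric costs), the minimum number of
gains when losses are forbidden (equivalently, the number of maximal
all-present clades), and the minimum number of losses when the trait is
granted a single gain at a chosen ancestor (a Dollo-style scenario).

Trees are rooted, binary or multifurcating; tips carry present/absent
states.  Only event *counts* are contracted — when several optimal
ancestral reconstructions exist, the count is still unique.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

__all__ = [
    "Node",
    "TipStateTree",
    "min_changes",
    "scenario_gains_no_losses",
    "scenario_losses_given_root_gain",
    "parsimony_report",
]

PRESENT, ABSENT = "present", "absent"
_INF = math.inf


@dataclass
class Node:
    label: str = ""
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Node"]:
        if self.is_tip:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def postorder(self) -> list["Node"]:
        out = []
        for c in self.children:
            out.extend(c.postorder())
        out.append(self)
        return out


@dataclass
class TipStateTree:
    """A rooted tree plus a present/absent state for every tip."""

    root: Node
    tip_states: dict[str, str]

    def __post_init__(self) -> None:
        for tip in self.root.tips():
            if tip.label not in self.tip_states:
                raise KeyError(f"tip {tip.label!r} has no state")
        for label, state in self.tip_states.items():
            if state not in (PRESENT, ABSENT):
                raise ValueError(f"state of {label!r} must be present/absent")

    @classmethod
    def from_newick(
        cls, newick: str, tip_states: Mapping[str, str | bool]
    ) -> "TipStateTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        root = _convert(tree.seed_node)
        states = {
            k: (PRESENT if v in (True, PRESENT, "1") else ABSENT)
            for k, v in tip_states.items()
        }
        return cls(root=root, tip_states=states)

    @classmethod
    def from_files(cls, newick_path: str, states_tsv: str) -> "TipStateTree":
        """Newick file + 2-column TSV (tip, present|absent|0|1)."""
        with open(newick_path) as fh:
            newick = fh.read()
        states: dict[str, str | bool] = {}
        with open(states_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tip, val = line.split("\t")[:2]
                if tip.lower() in ("tip", "species", "taxon"):
                    continue  # header
                states[tip] = val.strip().lower() in ("1", "present", "true")
        return cls.from_newick(newick, states)


def _convert(dnode: dendropy.Node) -> Node:
    label = ""
    if dnode.taxon is not None:
        label = dnode.taxon.label.replace(" ", "_")
    elif dnode.label:
        label = dnode.label
    return Node(label=label, children=[_convert(c) for c in dnode.child_nodes()])


def _sankoff_cost(node: Node, states: Mapping[str, str], cost: dict) -> tuple[float, float]:
    """(cost if node absent, cost if node present), minimised over descendants."""
    if node.is_tip:
        s = states[node.label]
        return (0.0, _INF) if s == ABSENT else (_INF, 0.0)
    ca = cp = 0.0
    for child in node.children:
        a, p = _sankoff_cost(child, states, cost)
        ca += min(a + cost[(ABSENT, ABSENT)], p + cost[(ABSENT, PRESENT)])
        cp += min(a + cost[(PRESENT, ABSENT)], p + cost[(PRESENT, PRESENT)])
    return ca, cp


_UNIT = {
    (ABSENT, ABSENT): 0.0, (PRESENT, PRESENT): 0.0,
    (ABSENT, PRESENT): 1.0, (PRESENT, ABSENT): 1.0,
}


def min_changes(tree: TipStateTree) -> int:
    """Minimum total state changes under unit symmetric costs (Sankoff).

    Equals Fitch's count on binary trees and handles multifurcations
    directly.
    """
    a, p = _sankoff_cost(tree.root, tree.tip_states, _UNIT)
    return int(min(a, p))


def scenario_gains_no_losses(tree: TipStateTree) -> int:
    """Minimum gains when the trait, once present, is never lost.

    With losses forbidden this is the number of maximal all-present clades.
    """
    cost = dict(_UNIT)
    cost[(PRESENT, ABSENT)] = _INF  # a present ancestor may not lose the trait
    a, p = _sankoff_cost(tree.root, tree.tip_states, cost)
    best = min(a, p + 1.0)  # a present root itself costs one gain
    if math.isinf(best):
        raise ValueError("no gains-only scenario exists for these states")
    return int(best)


def scenario_losses_given_root_gain(
    tree: TipStateTree, gain_node_label: str | None = None
) -> int:
    """Minimum losses given a single gain at ``gain_node_label`` (default root).

    The gain node starts in the present state and no further gain is
    allowed, so the count is the number of maximal all-absent clades below
    it.  A present tip outside the gain node's clade makes the scenario
    impossible -> hard error.
    """
    gain_node = tree.root
    if gain_node_label:
        gain_node = _find(tree.root, gain_node_label)
        if gain_node is None:
            raise KeyError(f"no node labelled {gain_node_label!r}")
        inside = {t.label for t in gain_node.tips()}
        outside_present = [
            lbl for lbl, s in tree.tip_states.items()
            if s == PRESENT and lbl not in inside
        ]
        if outside_present:
            raise ValueError(
                f"present tips outside the gain clade: {sorted(outside_present)}"
            )
    cost = dict(_UNIT)
    cost[(ABSENT, PRESENT)] = _INF  # no second gain below the gain node
    _, p = _sankoff_cost(gain_node, tree.tip_states, cost)
    if math.isinf(p):
        raise ValueError("no single-gain scenario exists for these states")
    return int(p)


def _find(node: Node, label: str) -> Node | None:
    if node.label == label:
        return node
    for c in node.children:
        found = _find(c, label)
        if found is not None:
            return found
    return None


def parsimony_report(
    tree: TipStateTree, gain_node_label: str | None = None
) -> dict:
    """JSON-ready comparison of the competing scenarios."""
    return {
        "n_tips": len(tree.root.tips()),
        "n_present": sum(1 for s in tree.tip_states.values() if s == PRESENT),
        "min_changes": min_changes(tree),
        "gains_only": scenario_gains_no_losses(tree),
        "losses_given_root_gain": scenario_losses_given_root_gain(
            tree, gain_node_label
        ),
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
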