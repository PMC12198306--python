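"""Gain/loss counting for the skipping character on rooted species trees."""

import itertools

import numpy as np
import pytest

from exonskip.datasets import (
    TETRAPOD_SKIPPING_PRESENT,
    TETRAPOD_TREE_NEWICK,
    tetrapod_skipping_fixture,
)
from exonskip.parsimony import (
    TipStateTree,
    min_changes,
    parsimony_report,
    scenario_gains_no_losses,
    scenario_losses_given_root_gain,
)


def _tree(newick, present):
    tips = _tip_labels(newick)
    return TipStateTree.from_newick(newick, {t: t in present for t in tips})


def _tip_labels(newick):
    import re

    return re.findall(r"[A-Za-z]\w*", newick)


def brute_force_min_changes(tree: TipStateTree) -> int:
    """Exhaustive enumeration over all internal-node state assignments."""
    nodes = tree.root.postorder()
    internal = [n for n in nodes if not n.is_tip]
    index = {id(n): i for i, n in enumerate(internal)}
    edges_ii, edges_it = [], []
    for n in internal:
        for c in n.children:
            if c.is_tip:
                edges_it.append((index[id(n)], tree.tip_states[c.label] == "present"))
            else:
                edges_ii.append((index[id(n)], index[id(c)]))
    k = len(internal)
    assert k <= 19
    assigns = np.arange(2 ** k, dtype=np.int64)
    bits = (assigns[:, None] >> np.arange(k)) & 1  # (2^k, k)
    changes = np.zeros(len(assigns), dtype=np.int64)
    for a, b in edges_ii:
        changes += bits[:, a] != bits[:, b]
    for a, tip_present in edges_it:
        changes += bits[:, a] != int(tip_present)
    return int(changes.min())


def test_uniform_tips_need_no_changes():
    t = _tree("((a,b),(c,d));", {"a", "b", "c", "d"})
    assert min_changes(t) == 0
    assert scenario_losses_given_root_gain(t) == 0


def test_two_tip_disagreement_costs_one():
    assert min_changes(_tree("(a,b);", {"a"})) == 1


def test_gains_only_trivial_cases():
    assert scenario_gains_no_losses(_tree("((a,b),(c,d));", set())) == 0
    assert scenario_gains_no_losses(_tree("((a,b),(c,d));", {"c"})) == 1
    # trait present everywhere: one ancestral gain
    assert scenario_gains_no_losses(_tree("((a,b),(c,d));", {"a", "b", "c", "d"})) == 1


def test_loss_of_one_whole_child_clade_costs_one():
    t = _tree("((a,b),(c,d));", {"a", "b"})
    assert scenario_losses_given_root_gain(t) == 1


def test_tetrapod_fixture_gains_vs_losses():
    """Four independent gains beat one ancestral gain plus six losses."""
    t = tetrapod_skipping_fixture()
    gains = scenario_gains_no_losses(t)
    losses = scenario_losses_given_root_gain(t)
    assert gains == 4
    assert losses == 6
    assert min_changes(t) == 4
    assert min_changes(t) <= min(gains, 1 + losses)


def test_fixture_minimum_equals_exhaustive_enumeration():
    t = tetrapod_skipping_fixture()
    assert min_changes(t) == brute_force_min_changes(t)


def test_gains_only_equals_maximal_all_present_clade_count():
    """Independent oracle: count clades whose tips are all 'present' and
    whose parent clade is not."""
    t = tetrapod_skipping_fixture()

    def all_present(node):
        return all(
            t.tip_states[x.label] == "present" for x in node.tips()
        )

    count = 0
    stack = [(t.root, False)]
    while stack:
        node, parent_all = stack.pop()
        here = all_present(node)
        if here and not parent_all:
            count += 1
        stack.extend((c, here) for c in node.children)
    assert scenario_gains_no_losses(t) == count == 4


@pytest.mark.parametrize("present", [
    {"a"}, {"a", "c"}, {"a", "b", "e"}, {"d", "e"}, set(), {"a", "b", "c", "d", "e"},
])
def test_multifurcation_matches_enumeration(present):
    t = _tree("((a,b,c),(d,e));", present)
    assert min_changes(t) == brute_force_min_changes(t)


def test_result_invariant_under_child_order_permutation():
    present = {"a", "c", "e"}
    base = _tree("((a,b),((c,d),e));", present)
    flipped = _tree("((e,(d,c)),(b,a));", present)
    for f in (min_changes, scenario_gains_no_losses, scenario_losses_given_root_gain):
        assert f(base) == f(flipped)


def test_random_binary_trees_match_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(10):
        labels = [f"t{i}" for i in range(8)]
        # random topology by sequential joining
        parts = [l for l in labels]
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(j)
            a = parts.pop(i)
            parts.append(f"({a},{b})")
        newick = parts[0] + ";"
        present = {l for l in labels if rng.random() < 0.5}
        t = _tree(newick, present)
        assert min_changes(t) == brute_force_min_changes(t)


def test_missing_tip_state_is_hard_error():
    with pytest.raises(KeyError):
        TipStateTree.from_newick("(a,b);", {"a": True})


def test_present_tip_outside_gain_clade_is_hard_error():
    t = TipStateTree.from_newick(
        "((a,b)left,(c,d)right);", {"a": True, "b": True, "c": True, "d": False}
    )
    with pytest.raises(ValueError, match="outside"):
        scenario_losses_given_root_gain(t, gain_node_label="left")


def test_report_and_file_round_trip(tmp_path):
    nw = tmp_path / "tree.nwk"
    nw.write_text(TETRAPOD_TREE_NEWICK + "\n")
    tsv = tmp_path / "states.tsv"
    lines = ["tip\tstate"]
    for tip in _tip_labels(TETRAPOD_TREE_NEWICK):
        state = "present" if tip in TETRAPOD_SKIPPING_PRESENT else "absent"
        lines.append(f"{tip}\t{state}")
    tsv.write_text("\n".join(lines) + "\n")
    t = TipStateTree.from_files(str(nw), str(tsv))
    report = parsimony_report(t)
    assert report == {
        "n_tips": 20,
        "n_present": 12,
        "min_changes": 4,
        "gains_only": 4,
        "losses_given_root_gain": 6,
    }
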