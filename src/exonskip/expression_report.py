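"""Control-normalised expression, presence calls, L/S subtotals, depth check.

Junction counts from libraries of wildly different depth are made comparable
by dividing by the same library's beta-actin (Actb) junction count and
reporting log10 of the ratio.  Per-gene counts are subtotalled into the long
(cassette-exon-containing, "L") and short (cassette-exon-skipping, "S")
isoform classes.  A depth report checks the confound that apparent isoform
absence merely reflects shallow sequencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "IsoformExpression",
    "normalized_expression",
    "aggregate_isoforms",
    "presence_call",
    "depth_report",
]


@dataclass(frozen=True)
class IsoformExpression:
    species_id: str
    gene_id: str
    isoform_class: str  # L | S
    raw_count: int
    actb_count: int
    log10_ratio: float | None
    present: bool


def normalized_expression(raw_count: int, actb_count: int) -> float | None:
    """log10(raw / Actb), or None when no reads support the isoform.

    A library with zero control reads cannot be interpreted at all (the
    control doubles as the library-quality gauge) -> hard error.
    """
    if raw_count < 0 or actb_count < 0:
        raise ValueError("counts must be non-negative")
    if actb_count == 0:
        raise ValueError("no control reads; library unusable")
    if raw_count == 0:
        return None
    return math.log10(raw_count / actb_count)


def presence_call(raw_count: int, min_reads: int = 1) -> bool:
    """Operational presence: at least ``min_reads`` perfect junction reads.

    The default of one read treats any perfect 30/30 junction match as
    detection; raw counts are always reported alongside so stricter
    thresholds can be applied downstream.
    """
    return raw_count >= min_reads


def aggregate_isoforms(
    per_query_counts: Mapping[str, int],
    cassette_containment: Mapping[str, bool],
) -> tuple[int, int]:
    """Subtotal junction-query counts into (L, S) by cassette-exon content.

    ``cassette_containment`` maps every query id to True (junction belongs
    to a cassette-including isoform) or False (skipping).  Every query must
    be mapped; L + S equals the sum of all counts.
    """
    unmapped = set(per_query_counts) - set(cassette_containment)
    if unmapped:
        raise KeyError(f"queries missing from containment map: {sorted(unmapped)}")
    L = sum(c for q, c in per_query_counts.items() if cassette_containment[q])
    S = sum(c for q, c in per_query_counts.items() if not cassette_containment[q])
    return L, S


def expression_row(
    species_id: str,
    gene_id: str,
    isoform_class: str,
    raw_count: int,
    actb_count: int,
    min_reads: int = 1,
) -> IsoformExpression:
    return IsoformExpression(
        species_id=species_id,
        gene_id=gene_id,
        isoform_class=isoform_class,
        raw_count=raw_count,
        actb_count=actb_count,
        log10_ratio=normalized_expression(raw_count, actb_count),
        present=presence_call(raw_count, min_reads),
    )


def depth_report(
    actb_totals: Mapping[str, int],
    s_presence: Mapping[str, bool],
) -> tuple[pd.DataFrame, float]:
    """Sequencing depth vs short-isoform presence across species.

    Returns the species table sorted by Actb total (ascending) and the
    rank-biserial association between depth and presence:
    ``2 * (mean rank among present - mean rank among absent) / n``.
    It is 0 when depth is constant (all ranks tied) or presence is uniform,
    and 1 when presence coincides exactly with the deepest half — the
    confound the report is designed to expose.  Diagnostic only; no
    hypothesis test.
    """
    species = sorted(actb_totals)
    if len(species) < 2:
        raise ValueError("depth report needs at least two species")
    missing = set(species) - set(s_presence)
    if missing:
        raise KeyError(f"species without presence call: {sorted(missing)}")
    depths = np.array([actb_totals[s] for s in species], dtype=float)
    present = np.array([bool(s_presence[s]) for s in species])
    table = (
        pd.DataFrame(
            {"species": species, "actb_reads": depths.astype(int), "s_present": present}
        )
        .sort_values(["actb_reads", "species"], kind="mergesort")
        .reset_index(drop=True)
    )
    n = len(species)
    if present.all() or not present.any():
        return table, 0.0
    ranks = rankdata(depths)
    assoc = 2.0 * (ranks[present].mean() - ranks[~present].mean()) / n
    return table, float(assoc)
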