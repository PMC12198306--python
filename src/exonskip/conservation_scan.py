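"""Sliding-window local similarity over protein alignments.

Each alignment column is scored over all unordered sequence pairs: 2 points
for an identity, 1 for a conservative substitution, 0 for a nonconservative
substitution or any gap — elevated to 3 per pair if, and only if, the column
is identical (and gap-free) across *all* rows.  The column's net score is
the mean over pairs, so it lies in [0, 3].  The local similarity of a
30-column window is the mean of its columns' net scores, plotted at the
window's centre.

Also houses the integer percent-identity arithmetic used for reporting
pairwise exon comparisons (e.g. 12/29 identities -> 41%).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_GROUPS",
    "SimilarityProfile",
    "column_net_score",
    "window_scan",
    "percent_identity",
]

#: Conservative-substitution groups ("strong" classes); swappable via config.
DEFAULT_GROUPS: tuple[str, ...] = ("ILMV", "FWY", "DENQ", "HKR", "AGPST", "C")

GAP = "-"


@dataclass
class SimilarityProfile:
    """Per-window local similarity scores of one alignment.

    ``points`` pairs each fully-contained window's centre column (1-based)
    with its score in [0, 3].  ``reference_positions``, when present, maps
    the same points onto a chosen reference row's residue numbering.
    """

    alignment_id: str
    window_length: int
    points: list[tuple[int, float]]
    reference_positions: list[tuple[int, float]] | None = None


def _group_of(groups: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for gi, g in enumerate(groups):
        for ch in g:
            out[ch] = gi
    return out


def column_net_score(
    alignment: Sequence[tuple[str, str]],
    column: int,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> float:
    """Mean pairwise score of one column (identity 2, conservative 1, else 0;
    3 per pair iff the column is identical across all rows)."""
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    chars = [row[column] for _, row in alignment]
    return _net_scores([c for c in chars], groups)


def _net_scores(chars: list[str], groups: Sequence[str]) -> float:
    n = len(chars)
    total_pairs = comb(n, 2)
    if chars.count(chars[0]) == n and chars[0] != GAP:
        return 3.0
    gmap = _group_of(groups)
    from collections import Counter

    counts = Counter(c for c in chars if c != GAP)
    ident = sum(comb(c, 2) for c in counts.values())
    group_counts = Counter()
    for res, c in counts.items():
        if res in gmap:
            group_counts[gmap[res]] += c
    within_group = sum(comb(c, 2) for c in group_counts.values())
    grouped_ident = sum(
        comb(c, 2) for res, c in counts.items() if res in gmap
    )
    conservative = within_group - grouped_ident
    return (2 * ident + conservative) / total_pairs


def _column_scores(
    alignment: Sequence[tuple[str, str]], groups: Sequence[str]
) -> np.ndarray:
    width = len(alignment[0][1])
    return np.array(
        [_net_scores([row[c] for _, row in alignment], groups) for c in range(width)]
    )


def window_scan(
    alignment: Sequence[tuple[str, str]],
    window_length: int = 30,
    groups: Sequence[str] = DEFAULT_GROUPS,
    alignment_id: str = "alignment",
    reference_row: int | None = None,
) -> SimilarityProfile:
    """Local similarity profile: mean net score of each fully-contained window.

    Windows advance one column at a time.  The centre of a window starting
    at 1-based column ``s`` is reported as ``s + window_length // 2`` (for
    the default even window of 30, fifteen columns in), so plots are
    reproducible bit for bit.  With ``reference_row`` set, centres are also
    mapped to that row's ungapped residue numbering (gap columns take the
    preceding residue's number).
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    width = len(alignment[0][1])
    if width < window_length:
        raise ValueError(
            f"alignment width {width} < window length {window_length}"
        )
    col = _column_scores(alignment, groups)
    windows = np.lib.stride_tricks.sliding_window_view(col, window_length)
    means = windows.mean(axis=1)
    half = window_length // 2
    points = [
        (start + 1 + half, float(means[start]))
        for start in range(width - window_length + 1)
    ]
    ref_points = None
    if reference_row is not None:
        row = alignment[reference_row][1]
        resno = np.cumsum([ch != GAP for ch in row])  # residue number at each column
        ref_points = [
            (int(resno[c - 1]), score) for c, score in points
        ]
    return SimilarityProfile(
        alignment_id=alignment_id,
        window_length=window_length,
        points=points,
        reference_positions=ref_points,
    )


def percent_identity(n_identical: int, n_compared: int) -> int:
    """Integer percent identity, rounded half away from zero."""
    if n_compared <= 0:
        raise ValueError("n_compared must be positive")
    if not 0 <= n_identical <= n_compared:
        raise ValueError("need 0 <= n_identical <= n_compared")
    import math

    return int(math.floor(100 * n_identical / n_compared + 0.5))


def profile_to_tsv(profile: SimilarityProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("center\tscore\n")
        for c, s in profile.points:
            fh.write(f"{c}\t{s:.6g}\n")


def plot_profile(
    profile: SimilarityProfile,
    path: str,
    shaded_intervals: Sequence[tuple[int, int]] = (),
) -> None:
    """Render the profile with optional shaded column intervals
    (transmembrane segments, exon boundaries, ...)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys = zip(*profile.points)
    fig, ax = plt.subplots(figsize=(8, 3))
    for lo, hi in shaded_intervals:
        ax.axvspan(lo, hi, color="0.85", zorder=0)
    ax.plot(xs, ys, lw=1.2)
    ax.set_xlabel("window centre (alignment column)")
    ax.set_ylabel("local similarity (0-3)")
    ax.set_ylim(0, 3.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
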