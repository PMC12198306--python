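"""Genetic-identity QC of junction-matched reads.

Matching a 30-nt junction query confirms only 30 nt of a read.  The rest of
the read is evidence about where the read really came from: a legitimate
transcript of the expected gene, a PCR rearrangement of that same gene, a
chimera with another gene of the same species or a foreign organism, vector
or barcode carry-over, or an unidentifiable short remnant.

Classification anchors the read on the junction 30-mer, extends the match
ungapped against the expected transcript in both directions allowing
scattered substitutions, and sends any unexplained leftover through an
exact-seed search of the reference sets in a fixed precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .gene_models import reverse_complement
from .junction_quant import MatchedRead

__all__ = [
    "QcParams",
    "QcCategory",
    "QC_LABELS",
    "classify_matched_read",
    "qc_summary",
]

QC_LABELS = (
    "clean",
    "rearranged_same_gene",
    "chimeric_same_species",
    "chimeric_foreign",
    "vector_or_barcode",
    "unidentified_short",
)


@dataclass(frozen=True)
class QcParams:
    """Thresholds of the identity check.

    max_subs: scattered substitutions tolerated in a fully explained read.
    min_leftover: nt below which an unexplained flank is unidentifiable.
    seed_len: exact-seed length for searching leftovers against references.
    """

    max_subs: int = 5
    min_leftover: int = 20
    seed_len: int = 16


@dataclass
class QcCategory:
    label: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in QC_LABELS:
            raise ValueError(f"unknown QC label {self.label!r}")


def _oriented(read: MatchedRead, k: int) -> tuple[str, int]:
    """Read sequence oriented so the query 30-mer appears forward, + its offset."""
    if read.orientation == "forward":
        return read.read_sequence, read.offset
    seq = reverse_complement(read.read_sequence)
    return seq, len(read.read_sequence) - read.offset - k


def _explained_interval(
    read_seq: str, anchor_off: int, k: int, transcript: str, t_pos: int,
    max_subs: int,
) -> tuple[int, int, int]:
    """Longest read interval containing the anchor explainable by the transcript.

    The read is aligned ungapped to the transcript via the anchor (read
    position ``anchor_off`` <-> transcript position ``t_pos``).  Returns
    ``(lo, hi, n_subs)``: the widest half-open read interval covering
    ``[anchor_off, anchor_off + k)`` whose positions all map inside the
    transcript with at most ``max_subs`` mismatches.
    """
    shift = t_pos - anchor_off  # read index + shift = transcript index
    lo_bound = max(0, -shift)
    hi_bound = min(len(read_seq), len(transcript) - shift)
    mism = [
        i for i in range(lo_bound, hi_bound)
        if read_seq[i] != transcript[i + shift]
    ]
    # two pointers over mismatch positions: widest window containing the
    # anchor interval with <= max_subs mismatches
    best = (anchor_off, anchor_off + k, 0)
    import bisect

    lo = lo_bound
    j0 = 0  # index of first mismatch >= lo
    for lo in range(lo_bound, anchor_off + 1):
        j0 = bisect.bisect_left(mism, lo)
        # furthest hi with <= max_subs mismatches in [lo, hi)
        j_end = j0 + max_subs
        hi = hi_bound if j_end >= len(mism) else mism[j_end]
        if hi < anchor_off + k:
            continue
        if hi - lo > best[1] - best[0]:
            n = bisect.bisect_left(mism, hi) - j0
            best = (lo, hi, n)
        if lo == lo_bound and hi == hi_bound:
            break  # cannot do better
    return best


def _seed_hits(
    leftover: str, refs: Mapping[str, str], seed_len: int
) -> list[str]:
    """Reference ids hit by any exact seed of the leftover, either strand."""
    if len(leftover) < seed_len:
        return []
    seeds = {
        leftover[i:i + seed_len]
        for i in range(0, len(leftover) - seed_len + 1, max(1, seed_len // 2))
    }
    seeds |= {reverse_complement(s) for s in seeds}
    hits = []
    for rid, seq in refs.items():
        s = seq.upper()
        if any(k in s for k in seeds):
            hits.append(rid)
    return hits


def classify_matched_read(
    read: MatchedRead,
    expected_transcript: str,
    same_gene_refs: Mapping[str, str],
    same_species_refs: Mapping[str, str],
    foreign_refs: Mapping[str, str],
    vector_refs: Mapping[str, str],
    params: QcParams = QcParams(),
    k: int = 30,
) -> QcCategory:
    """Assign exactly one identity category to a junction-matched read.

    ``expected_transcript`` must contain the junction 30-mer (a missing
    junction is a configuration bug, not a read property).  ``same_gene_refs``
    are transcripts of the expected gene (for detecting strand-switch /
    gapped rearrangements); ``same_species_refs`` are the species' other
    genes.  Precedence on multiple leftover hits: vector > rearranged
    same-gene > same-species > foreign; ambiguity is recorded in evidence.
    """
    seq, off = _oriented(read, k)
    kmer = seq[off:off + k]
    transcript = expected_transcript.upper()
    t_pos = transcript.find(kmer)
    if t_pos == -1:
        raise ValueError(
            f"expected transcript lacks the junction 30-mer of query "
            f"{read.query_id} (configuration bug)"
        )
    lo, hi, n_subs = _explained_interval(
        seq, off, k, transcript, t_pos, params.max_subs
    )
    evidence: dict = {
        "explained_span": (lo, hi),
        "substitutions": n_subs,
        "matched_span": (off, off + k),
    }
    if lo == 0 and hi == len(seq):
        return QcCategory("clean", evidence)

    left, right = seq[:lo], seq[hi:]
    leftover = left if len(left) >= len(right) else right
    evidence["leftover_span"] = (0, lo) if leftover is left else (hi, len(seq))
    evidence["leftover_len"] = len(leftover)
    if len(leftover) < params.min_leftover:
        return QcCategory("unidentified_short", evidence)

    ordered = (
        ("vector_or_barcode", vector_refs),
        ("rearranged_same_gene", same_gene_refs),
        ("chimeric_same_species", same_species_refs),
        ("chimeric_foreign", foreign_refs),
    )
    all_hits = {
        label: _seed_hits(leftover, refs, params.seed_len)
        for label, refs in ordered
    }
    evidence["reference_hits"] = {k_: v for k_, v in all_hits.items() if v}
    if sum(bool(v) for v in all_hits.values()) > 1:
        evidence["ambiguous"] = True
    for label, _ in ordered:
        if all_hits[label]:
            evidence["best_hit"] = all_hits[label][0]
            return QcCategory(label, evidence)
    return QcCategory("unidentified_short", evidence)


def qc_summary(
    categories: Iterable[QcCategory],
    read_lengths: Iterable[int] = (),
) -> dict:
    """Category counts, rounded integer percent fractions, mean read length.

    Counts always sum to the number of inputs.  Mean length = total nt /
    read count, rounded to the nearest integer; absent for empty input.
    """
    counts = {label: 0 for label in QC_LABELS}
    n = 0
    for c in categories:
        counts[c.label] += 1
        n += 1
    lengths = list(read_lengths)
    summary = {
        "n_reads": n,
        "counts": counts,
        "fractions_percent": {
            label: _round_half_up(100 * c_ / n) if n else 0
            for label, c_ in counts.items()
        },
        "mean_read_length": (
            _round_half_up(sum(lengths) / len(lengths)) if lengths else None
        ),
    }
    return summary


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
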