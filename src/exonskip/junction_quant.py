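"""Exon-junction query (ej-RNA) design and perfect-match read counting.

An ej-RNA is a 30-nt query spanning one splice junction: the last 15 nt of
the upstream exon followed by the first 15 nt of the downstream exon.  A
read supports the junction iff it contains the query with a perfect 30/30
match and no gaps, on either strand by default.  Counting is read-level: a
read increments a query's count at most once however many times the 30-mer
occurs in it.

The production scan indexes every query 30-mer (and its reverse complement)
in a hash table and slides a 30-nt window over each read; the test suite
checks it byte-for-byte against a naive per-read, per-query substring scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gene_models import GeneModel, IsoformModel, exon_sequence, reverse_complement

__all__ = [
    "EjRNA",
    "MatchedRead",
    "UniquenessReport",
    "design_ejrna",
    "check_uniqueness",
    "count_junction_reads",
    "naive_count_junction_reads",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class EjRNA:
    """A junction query: ``flank`` nt of upstream exon + ``flank`` nt of downstream."""

    query_id: str
    gene_id: str
    junction_type: str  # inclusion | skipping | control
    upstream_exon_id: str
    downstream_exon_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 != 0:
            raise ValueError("ej-RNA length must be even (equal flanks)")
        if self.junction_type not in ("inclusion", "skipping", "control"):
            raise ValueError(f"unknown junction type {self.junction_type!r}")


@dataclass(frozen=True)
class MatchedRead:
    """A read containing an ej-RNA 30-mer as a perfect, gap-free match."""

    read_id: str
    query_id: str
    offset: int  # 0-based position of the 30-mer in the read as stored
    orientation: str  # forward | reverse_complement
    read_sequence: str

    def matched_kmer(self, k: int = 30) -> str:
        """The query as recovered from the read (re-verification hook)."""
        s = self.read_sequence[self.offset:self.offset + k]
        return s if self.orientation == "forward" else reverse_complement(s)


@dataclass
class UniquenessReport:
    query_id: str
    unique: bool
    hits: list[str] = field(default_factory=list)  # transcript ids containing the 30-mer
    screened: bool = True


def design_ejrna(
    model: GeneModel,
    upstream_exon_id: str,
    downstream_exon_id: str,
    sequences: Mapping[str, str],
    flank: int = 15,
    junction_type: str | None = None,
    query_id: str | None = None,
) -> EjRNA:
    """Build the 2x``flank`` junction query joining two exons of one gene.

    ``junction_type`` is inferred when omitted: adjacent exons -> inclusion,
    exons separated by exactly one cassette exon -> skipping.  Control
    queries (e.g. the beta-actin exon 3|4 junction) pass it explicitly.
    """
    iu = model.exon_index(upstream_exon_id)
    idn = model.exon_index(downstream_exon_id)
    if idn <= iu:
        raise ValueError("downstream exon must follow upstream exon")
    up_seq = exon_sequence(model, model.exons[iu], sequences)
    dn_seq = exon_sequence(model, model.exons[idn], sequences)
    if len(up_seq) < flank or len(dn_seq) < flank:
        raise ValueError(
            f"exon shorter than flank={flank} nt "
            f"({upstream_exon_id}: {len(up_seq)}, {downstream_exon_id}: {len(dn_seq)})"
        )
    if junction_type is None:
        gap = idn - iu - 1
        if gap == 0:
            junction_type = "inclusion"
        elif gap == 1:
            junction_type = "skipping"
        else:
            raise ValueError(
                "cannot infer junction type for exons more than one apart; "
                "pass junction_type explicitly"
            )
    qid = query_id or f"{model.gene_id}:{upstream_exon_id}|{downstream_exon_id}"
    return EjRNA(
        query_id=qid,
        gene_id=model.gene_id,
        junction_type=junction_type,
        upstream_exon_id=upstream_exon_id,
        downstream_exon_id=downstream_exon_id,
        sequence=up_seq[-flank:] + dn_seq[:flank],
    )


def check_uniqueness(
    ejrna: EjRNA,
    transcripts: Mapping[str, str],
    intended: Iterable[str] = (),
) -> UniquenessReport:
    """Scan a transcript set (both strands) for the query 30-mer.

    ``unique`` iff only the intended isoform transcript(s) contain it.  An
    empty transcript set yields an 'unscreened' report.
    """
    if not transcripts:
        return UniquenessReport(ejrna.query_id, unique=False, screened=False)
    q = ejrna.sequence.upper()
    rc = reverse_complement(q)
    hits = [
        tid for tid, seq in transcripts.items()
        if q in seq.upper() or rc in seq.upper()
    ]
    intended = set(intended)
    return UniquenessReport(
        query_id=ejrna.query_id,
        unique=bool(hits) and set(hits) <= intended if intended else len(hits) <= 1,
        hits=hits,
    )


def _query_index(
    queries: Sequence[EjRNA], strand_mode: str
) -> tuple[dict[str, list[tuple[str, str]]], int]:
    if strand_mode not in ("both", "forward"):
        raise ValueError("strand_mode must be 'both' or 'forward'")
    seen_ids: set[str] = set()
    lengths = {len(q.sequence) for q in queries}
    if len(lengths) > 1:
        raise ValueError("all queries must share one length")
    k = lengths.pop() if lengths else 0
    index: dict[str, list[tuple[str, str]]] = {}
    for q in queries:
        if q.query_id in seen_ids:
            raise ValueError(f"duplicate query_id {q.query_id!r}")
        seen_ids.add(q.query_id)
        index.setdefault(q.sequence.upper(), []).append((q.query_id, "forward"))
        if strand_mode == "both":
            index.setdefault(reverse_complement(q.sequence.upper()), []).append(
                (q.query_id, "reverse_complement")
            )
    return index, k


def count_junction_reads(
    reads: Iterable[tuple[str, str]],
    queries: Sequence[EjRNA],
    strand_mode: str = "both",
) -> tuple[dict[str, int], list[MatchedRead]]:
    """Count reads containing each query with a perfect gap-free match.

    ``reads`` are ``(read_id, sequence)`` pairs (FASTQ qualities are
    irrelevant to an exact-match criterion).  Counts over disjoint read
    batches are additive; reads shorter than the query length contribute
    zero; reads with characters outside ACGTN are skipped with a warning.
    A read matching two distinct queries is counted for each, with a
    uniqueness warning.
    """
    index, k = _query_index(queries, strand_mode)
    counts = {q.query_id: 0 for q in queries}
    matched: list[MatchedRead] = []
    if k == 0:
        return counts, matched
    for read_id, seq in reads:
        s = seq.upper()
        if not _VALID.issuperset(s):
            warnings.warn(f"read {read_id}: non-ACGTN characters, skipped", stacklevel=2)
            continue
        hit_queries: dict[str, MatchedRead] = {}
        for off in range(len(s) - k + 1):
            for qid, orient in index.get(s[off:off + k], ()):
                if qid not in hit_queries:  # read-level: first occurrence only
                    hit_queries[qid] = MatchedRead(read_id, qid, off, orient, s)
        if len(hit_queries) > 1:
            warnings.warn(
                f"read {read_id} matches multiple queries "
                f"{sorted(hit_queries)}; check query uniqueness",
                stacklevel=2,
            )
        for qid, m in hit_queries.items():
            counts[qid] += 1
            matched.append(m)
    return counts, matched


def naive_count_junction_reads(
    reads: Iterable[tuple[str, str]],
    queries: Sequence[EjRNA],
    strand_mode: str = "both",
) -> tuple[dict[str, int], list[MatchedRead]]:
    """Reference per-read, per-query substring scan (the counting oracle)."""
    counts = {q.query_id: 0 for q in queries}
    if len(counts) != len(queries):
        raise ValueError("duplicate query_id")
    matched: list[MatchedRead] = []
    for read_id, seq in reads:
        s = seq.upper()
        if not _VALID.issuperset(s):
            continue
        for q in queries:
            qs = q.sequence.upper()
            f = s.find(qs)
            r = s.find(reverse_complement(qs)) if strand_mode == "both" else -1
            if f == -1 and r == -1:
                continue
            # earliest occurrence wins; forward breaks ties
            if f != -1 and (r == -1 or f <= r):
                m = MatchedRead(read_id, q.query_id, f, "forward", s)
            else:
                m = MatchedRead(read_id, q.query_id, r, "reverse_complement", s)
            matched.append(m)
            counts[q.query_id] += 1
    return counts, matched
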