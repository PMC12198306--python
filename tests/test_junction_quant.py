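"""ej-RNA design and perfect-match (30/30, gap-free) read counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exonskip.gene_models import reverse_complement
from exonskip.junction_quant import (
    EjRNA,
    check_uniqueness,
    count_junction_reads,
    design_ejrna,
    naive_count_junction_reads,
)

from conftest import random_seq, toy_gene


def _queries(fx):
    model = fx.models["spA_drd2"]
    ex = [e.exon_id for e in model.exons]
    incl = design_ejrna(model, ex[4], ex[5], fx.sequences)
    skip = design_ejrna(model, ex[4], ex[6], fx.sequences)
    return incl, skip


def test_design_is_flank_concatenation():
    """Last 15 nt of the upstream exon + first 15 nt of the downstream exon."""
    model, seqs = toy_gene((120, 87, 99), seed=3)
    chrom = seqs["chrT"]
    e1, e2 = model.exons[0], model.exons[1]
    q = design_ejrna(model, e1.exon_id, e2.exon_id, seqs)
    assert len(q.sequence) == 30
    assert q.sequence == chrom[e1.end - 15:e1.end] + chrom[e2.start:e2.start + 15]
    assert q.junction_type == "inclusion"


def test_inclusion_and_skipping_queries_share_upstream_flank(fixture_gene):
    incl, skip = _queries(fixture_gene)
    assert incl.sequence[:15] == skip.sequence[:15]
    assert incl.sequence != skip.sequence
    assert (incl.junction_type, skip.junction_type) == ("inclusion", "skipping")


def test_control_junction_design(fixture_gene):
    """The control gene is queried at its exon 3 | exon 4 junction."""
    fx = fixture_gene
    control = fx.models["spA_actb"]
    cex = [e.exon_id for e in control.exons]
    q = design_ejrna(control, cex[2], cex[3], fx.sequences, junction_type="control")
    t = fx.transcripts["spA_actb_t"]
    assert len(q.sequence) == 30 and q.sequence in t
    assert q.junction_type == "control"


def test_exon_shorter_than_flank_is_hard_error():
    model, seqs = toy_gene((120, 9, 99), seed=2)
    with pytest.raises(ValueError, match="shorter than flank"):
        design_ejrna(model, model.exons[0].exon_id, model.exons[1].exon_id, seqs)


def test_unknown_exon_id_is_hard_error(fixture_gene):
    model = fixture_gene.models["spA_drd2"]
    with pytest.raises(KeyError):
        design_ejrna(model, "nope", model.exons[1].exon_id, fixture_gene.sequences)


def test_uniqueness_against_own_isoforms(fixture_gene):
    fx = fixture_gene
    incl, skip = _queries(fx)
    rep = check_uniqueness(incl, fx.transcripts, intended={"spA_drd2_L"})
    assert rep.unique and rep.hits == ["spA_drd2_L"]
    # the inclusion 30-mer spans a junction the skipping transcript lacks
    assert incl.sequence not in fx.transcripts["spA_drd2_S"]
    rep_s = check_uniqueness(skip, fx.transcripts, intended={"spA_drd2_S"})
    assert rep_s.unique and rep_s.hits == ["spA_drd2_S"]


def test_planted_query_breaks_uniqueness(fixture_gene):
    fx = fixture_gene
    incl, _ = _queries(fx)
    polluted = dict(fx.transcripts)
    polluted["intruder"] = "ACGT" * 10 + incl.sequence + "TTTT"
    rep = check_uniqueness(incl, polluted, intended={"spA_drd2_L"})
    assert not rep.unique and "intruder" in rep.hits


def test_empty_transcript_set_is_unscreened(fixture_gene):
    incl, _ = _queries(fixture_gene)
    assert not check_uniqueness(incl, {}).screened


def _q(seq, qid="q1"):
    return EjRNA(qid, "g", "inclusion", "e1", "e2", seq)


def test_exact_match_counts_once_even_with_two_occurrences():
    rng = np.random.default_rng(0)
    q = _q(random_seq(rng, 30))
    read = "AAAA" + q.sequence + "CC" + q.sequence
    counts, matched = count_junction_reads([("r1", read)], [q])
    assert counts == {"q1": 1}
    assert matched[0].offset == 4 and matched[0].orientation == "forward"


def test_any_single_substitution_kills_the_match():
    rng = np.random.default_rng(1)
    q = _q(random_seq(rng, 30))
    for pos in range(30):
        for alt in "ACGT".replace(q.sequence[pos], ""):
            mutated = q.sequence[:pos] + alt + q.sequence[pos + 1:]
            counts, _ = count_junction_reads([("r", "TT" + mutated + "GG")], [q])
            assert counts["q1"] == 0


def test_reverse_complement_counts_only_in_both_mode():
    rng = np.random.default_rng(2)
    q = _q(random_seq(rng, 30))
    read = "GG" + reverse_complement(q.sequence) + "AA"
    both, matched = count_junction_reads([("r", read)], [q], strand_mode="both")
    fwd, _ = count_junction_reads([("r", read)], [q], strand_mode="forward")
    assert both == {"q1": 1} and fwd == {"q1": 0}
    assert matched[0].orientation == "reverse_complement"
    assert matched[0].matched_kmer() == q.sequence


def test_short_and_invalid_reads_contribute_zero():
    rng = np.random.default_rng(3)
    q = _q(random_seq(rng, 30))
    with pytest.warns(UserWarning, match="non-ACGTN"):
        counts, _ = count_junction_reads(
            [("short", q.sequence[:29]), ("bad", "X" + q.sequence)], [q]
        )
    assert counts["q1"] == 0


def test_duplicate_query_id_is_hard_error():
    rng = np.random.default_rng(4)
    a, b = _q(random_seq(rng, 30), "dup"), _q(random_seq(rng, 30), "dup")
    with pytest.raises(ValueError, match="duplicate"):
        count_junction_reads([], [a, b])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_indexed_scan_equals_naive_oracle(seed):
    """The hash-indexed multi-pattern scan is byte-identical to the naive
    per-read, per-query substring scan."""
    rng = np.random.default_rng(seed)
    queries = [_q(random_seq(rng, 30), f"q{i}") for i in range(4)]
    reads = []
    for i in range(120):
        seq = random_seq(rng, int(rng.integers(20, 140)))
        if rng.random() < 0.5:
            q = queries[rng.integers(0, 4)].sequence
            if rng.random() < 0.5:
                q = reverse_complement(q)
            pos = int(rng.integers(0, max(1, len(seq) - 29)))
            seq = seq[:pos] + q + seq[pos + 30:]
        reads.append((f"r{i}", seq))
    fast_counts, fast_matched = count_junction_reads(reads, queries)
    slow_counts, slow_matched = naive_count_junction_reads(reads, queries)
    assert fast_counts == slow_counts
    assert set(fast_matched) == set(slow_matched)
    # every matched read re-verifies against its query
    by_id = {q.query_id: q.sequence for q in queries}
    for m in fast_matched:
        assert m.matched_kmer() == by_id[m.query_id]


def test_counts_are_additive_over_read_batches():
    rng = np.random.default_rng(9)
    q = _q(random_seq(rng, 30))
    batch1 = [("a", "TT" + q.sequence), ("b", random_seq(rng, 60))]
    batch2 = [("c", q.sequence + "GGG")]
    c1, _ = count_junction_reads(batch1, [q])
    c2, _ = count_junction_reads(batch2, [q])
    call, _ = count_junction_reads(batch1 + batch2, [q])
    assert call["q1"] == c1["q1"] + c2["q1"] == 2
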