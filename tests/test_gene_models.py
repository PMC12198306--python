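"""Gene architecture: intron phases, splicing, translation, GFF3 round trip."""

import warnings

import pytest

from exonskip.gene_models import (
    NON_CODING_PHASE,
    GeneModel,
    IsoformModel,
    intron_phase,
    read_gene_models,
    reverse_complement,
    splice_transcript,
    translate_cds,
    translate_isoform,
    write_gff3,
)

from conftest import toy_gene


@pytest.mark.parametrize(
    "cds_lens, expected_phases",
    [
        ((120, 87, 99), (0, 0)),        # 120 % 3 = 0, 207 % 3 = 0
        ((100, 87, 98), (1, 1)),        # 100 % 3 = 1
        ((88, 2, 90), (1, 0)),
    ],
)
def test_intron_phases_are_cumulative_cds_mod_3(cds_lens, expected_phases):
    model, _ = toy_gene(cds_lens)
    assert tuple(i.phase for i in model.introns) == expected_phases
    for idx, want in enumerate(expected_phases):
        assert intron_phase(model, idx) == want


def test_intron_phase_index_out_of_range():
    model, _ = toy_gene((120, 87, 99))
    with pytest.raises(IndexError):
        intron_phase(model, 5)


def test_utr_only_intron_gets_noncoding_sentinel():
    # first exon entirely 5'-UTR: the intron after it does not touch the CDS
    model, _ = toy_gene((0, 90, 96), utr5=40)
    assert model.introns[0].phase == NON_CODING_PHASE
    assert model.introns[1].phase == 0


def test_minus_strand_twin_has_identical_phases_and_transcript():
    """A gene and its reverse-complement encoding are the same gene."""
    plus, seqs = toy_gene((120, 87, 99), seed=7)
    chrom = seqs["chrT"]
    L = len(chrom)
    rc_seqs = {"chrT": reverse_complement(chrom)}
    minus = GeneModel(
        gene_id="toy_rc", species_id="toysp", seqid="chrT", strand="-",
        exons=[
            type(e)(e.exon_id, L - e.end, L - e.start, e.cds_len)
            for e in plus.exons
        ],
        introns=[
            type(i)(i.intron_id, L - i.end, L - i.start, i.phase)
            for i in plus.introns
        ],
        cds_offset=plus.cds_offset,
    )
    assert [i.phase for i in minus.introns] == [i.phase for i in plus.introns]
    iso_p = IsoformModel("p", plus.gene_id, tuple(e.exon_id for e in plus.exons))
    iso_m = IsoformModel("m", minus.gene_id, tuple(e.exon_id for e in minus.exons))
    assert splice_transcript(plus, iso_p, seqs) == splice_transcript(minus, iso_m, rc_seqs)


def test_splice_lengths_and_skipping_subtraction(fixture_gene):
    fx = fixture_gene
    model = fx.models["spA_drd2"]
    incl = fx.transcripts["spA_drd2_L"]
    skip = fx.transcripts["spA_drd2_S"]
    assert len(incl) == sum(e.length for e in model.exons)
    cassette = model.exon(fx.cassette_exon_id)
    assert len(skip) == len(incl) - cassette.length


def test_phase0_flanked_skipping_preserves_frame(fixture_gene):
    fx = fixture_gene
    model = fx.models["spA_drd2"]
    assert model.introns[4].phase == 0 and model.introns[5].phase == 0
    _, premature = translate_isoform(
        model, fx.isoforms["spA_drd2_S"], fx.sequences
    )
    assert not premature


@pytest.mark.parametrize(
    "seq, offset, protein, flag",
    [
        ("ATGAAATAA", 0, "MK", False),
        ("ATGTAAAAATAA", 0, "M", True),
        ("GGATGAAATAA", 2, "MK", False),
    ],
)
def test_translate_cds_examples(seq, offset, protein, flag):
    assert translate_cds(seq, offset) == (protein, flag)


def test_translate_ambiguity_becomes_X():
    aa, flag = translate_cds("ATGANATAA")
    assert aa == "MX" and not flag


def test_pseudogene_mid_orf_stop_is_flagged(fixture_gene):
    """An in-frame stop inside the ORF marks a pseudogene candidate."""
    fx = fixture_gene
    t = fx.transcripts["spA_drd2_L"]
    model = fx.models["spA_drd2"]
    broken = t[: model.cds_offset + 90] + "TGA" + t[model.cds_offset + 93:]
    _, flag = translate_cds(broken, model.cds_offset, model.cds_length)
    assert flag


def test_incomplete_orf_is_warning_flag_not_error():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model, _ = toy_gene((100, 87, 99))  # total 286, not divisible by 3
    assert model.incomplete_orf
    assert any("not divisible by 3" in str(w.message) for w in caught)


def test_gff3_round_trip_preserves_structure_and_sequence(tmp_path, fixture_gene):
    fx = fixture_gene
    path = str(tmp_path / "genes.gff3")
    write_gff3(fx.models.values(), path)
    reread = read_gene_models(path, fx.sequences, species_id="spA")
    assert set(reread) == set(fx.models)
    for gid, orig in fx.models.items():
        got = reread[gid]
        assert [(e.exon_id, e.start, e.end, e.cds_len) for e in got.exons] == [
            (e.exon_id, e.start, e.end, e.cds_len) for e in orig.exons
        ]
        assert [i.phase for i in got.introns] == [i.phase for i in orig.introns]
        assert got.cds_offset == orig.cds_offset
    for iso_id, iso in fx.isoforms.items():
        assert (
            splice_transcript(reread[iso.gene_id], iso, fx.sequences)
            == fx.transcripts[iso_id]
        )


def test_missing_reference_sequence_is_hard_error(tmp_path, fixture_gene):
    fx = fixture_gene
    path = str(tmp_path / "genes.gff3")
    write_gff3(fx.models.values(), path)
    with pytest.raises(KeyError, match="absent sequence"):
        read_gene_models(path, {}, species_id="spA")


def test_json_round_trip(fixture_gene):
    model = fixture_gene.models["spA_drd2"]
    again = GeneModel.from_json(model.to_json())
    assert again == model
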