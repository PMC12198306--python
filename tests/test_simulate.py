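"""Seeded generator: determinism, mixture arithmetic, artifact construction."""

import numpy as np
import pandas as pd
import pytest

from exonskip.gene_models import translate_isoform
from exonskip.junction_quant import count_junction_reads, design_ejrna
from exonskip.simulate import (
    ARTIFACT_CATEGORIES,
    DEPTH_TIERS,
    GeneFixtureConfig,
    SimulationScenario,
    SpeciesLibrarySpec,
    read_fastq,
    scenario_from_table,
    simulate_gene_fixture,
    simulate_reads,
    write_fastq,
)


def _junction_queries(fixture, ci=5):
    model = fixture.models[f"{fixture.species_id}_drd2"]
    ex = [e.exon_id for e in model.exons]
    incl = design_ejrna(model, ex[ci - 1], ex[ci], fixture.sequences)
    skip = design_ejrna(model, ex[ci - 1], ex[ci + 1], fixture.sequences)
    return incl, skip


def test_fixture_is_byte_deterministic():
    a = simulate_gene_fixture(seed=99, species_id="spD")
    b = simulate_gene_fixture(seed=99, species_id="spD")
    assert a.sequences == b.sequences and a.transcripts == b.transcripts
    c = simulate_gene_fixture(seed=100, species_id="spD")
    assert a.sequences != c.sequences


def test_default_fixture_has_phase0_flanked_short_cassette(fixture_gene):
    model = fixture_gene.models["spA_drd2"]
    ci = model.exon_index(fixture_gene.cassette_exon_id)
    assert model.introns[ci - 1].phase == 0
    assert model.introns[ci].phase == 0
    codons = model.exons[ci].cds_len // 3
    assert 24 <= codons <= 33
    assert model.cds_length % 3 == 0


def test_configured_flank_phases_break_frame_on_skipping():
    fx = simulate_gene_fixture(
        GeneFixtureConfig(flank_phases=(0, 1)), seed=4, species_id="spE"
    )
    model = fx.models["spE_drd2"]
    ci = model.exon_index(fx.cassette_exon_id)
    assert (model.introns[ci - 1].phase, model.introns[ci].phase) == (0, 1)
    _, premature = translate_isoform(
        model, fx.isoforms["spE_drd2_S"], fx.sequences
    )
    assert premature


def test_cassette_below_one_codon_is_hard_error():
    with pytest.raises(ValueError, match="codon"):
        simulate_gene_fixture(GeneFixtureConfig(cassette_codons=0), seed=1)


def test_reads_are_byte_deterministic_through_fastq(tmp_path):
    sc = SimulationScenario(
        seed=7, species=[SpeciesLibrarySpec("spF", n_reads=500)]
    )
    p1, p2 = str(tmp_path / "a.fastq"), str(tmp_path / "b.fastq")
    for p in (p1, p2):
        reads, _ = simulate_reads(sc)
        write_fastq(reads, p)
    assert open(p1, "rb").read() == open(p2, "rb").read()
    assert read_fastq(p1) == reads


def test_zero_pi_s_yields_no_skipping_junction_matches():
    sc = SimulationScenario(
        seed=21, species=[SpeciesLibrarySpec("spG", pi_s=0.0, n_reads=4000,
                                             error_rate=0.0)]
    )
    reads, truth = simulate_reads(sc)
    incl, skip = _junction_queries(sc.fixture_for(0))
    counts, _ = count_junction_reads(reads, [incl, skip])
    assert counts[skip.query_id] == 0
    assert counts[incl.query_id] > 0
    assert not truth.isoform.str.endswith("_S").any()


def test_junction_count_matches_positional_arithmetic():
    """With no errors or artifacts, the junction-spanning count follows the
    read-placement combinatorics within 4-sigma binomial bounds."""
    spec = SpeciesLibrarySpec(
        "spH", pi_s=0.0, n_reads=12_000, error_rate=0.0,
        chimera_fraction=0.0, control_fraction=0.0,
    )
    sc = SimulationScenario(seed=5, species=[spec])
    reads, truth = simulate_reads(sc)
    fx = sc.fixture_for(0)
    incl, skip = _junction_queries(fx)
    counts, _ = count_junction_reads(reads, [incl, skip])
    t = fx.transcripts["spH_drd2_L"]
    model = fx.models["spH_drd2"]
    boundary = sum(e.length for e in model.exons[:5])
    # P(span | length L) for a uniform start: the start must land in
    # [b+15-L, b-15], clipped to the valid start range [0, T-L]
    T = len(t)
    lengths = truth.length.to_numpy()
    valid = (
        np.minimum(boundary - 15, T - lengths)
        - np.maximum(0, boundary + 15 - lengths) + 1
    ).clip(0)
    p = valid / (T - lengths + 1)
    expect = float(p.sum())
    sd = float(np.sqrt((p * (1 - p)).sum()))
    assert abs(counts[incl.query_id] - expect) <= 4 * sd


def test_chimera_mix_covers_all_categories_with_intact_junction():
    spec = SpeciesLibrarySpec("spI", pi_s=0.5, n_reads=20_000,
                              chimera_fraction=0.25, error_rate=0.0)
    sc = SimulationScenario(seed=13, species=[spec])
    reads, truth = simulate_reads(sc)
    artifacts = truth[truth.category != "clean"]
    assert set(artifacts.category) == set(ARTIFACT_CATEGORIES)
    incl, skip = _junction_queries(sc.fixture_for(0))
    counts, matched = count_junction_reads(reads, [incl, skip])
    matched_ids = {m.read_id for m in matched}
    assert set(artifacts.read_id) <= matched_ids


def test_scenario_from_table_encodes_presence_pattern():
    table = pd.DataFrame({
        "species": [f"s{i}" for i in range(6)],
        "skipping": [True, False, True, False, False, True],
        "depth_tier": ["low", "medium", "high"] * 2,
    })
    sc = scenario_from_table(table, seed=3)
    assert len(sc.species) == 6
    assert sum(s.pi_s > 0 for s in sc.species) == 3
    assert [s.n_reads for s in sc.species] == [
        DEPTH_TIERS[t] for t in ["low", "medium", "high"] * 2
    ]


def test_empty_table_gives_empty_scenario():
    table = pd.DataFrame(columns=["species", "skipping", "depth_tier"])
    sc = scenario_from_table(table, seed=3)
    assert sc.species == []
    reads, truth = simulate_reads(sc)
    assert reads == [] and truth.empty


def test_unknown_depth_tier_is_hard_error():
    table = pd.DataFrame(
        {"species": ["x"], "skipping": [True], "depth_tier": ["abyssal"]}
    )
    with pytest.raises(KeyError, match="abyssal"):
        scenario_from_table(table)
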