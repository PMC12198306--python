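"""Seeded synthetic fixtures: gene models, isoform mixtures, reads, artifacts.

Every pipeline stage is testable without touching an archive: this module
fabricates, deterministically from a seed,

* a target gene with a short cassette exon (24-33 codons by default)
  flanked by two phase-0 introns, plus a beta-actin-like control gene;
* inclusion/skipping transcript mixtures at a configurable skipping
  proportion pi_S;
* reads of mean length 108 nt with iid per-base substitution errors; and
* a configurable fraction of chimeric artifact reads spanning five
  categories (same-gene rearrangement, same-species fusion, foreign fusion,
  vector/barcode carry-over, unidentifiable short leftover), each built
  around an intact junction 30-mer so the counting stage still retrieves it,
  and each carrying its truth label.

Byte-identical output for a fixed seed is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_models import (
    Exon,
    GeneModel,
    IsoformModel,
    build_gene_model,
    reverse_complement,
)

__all__ = [
    "GeneFixtureConfig",
    "SpeciesLibrarySpec",
    "SimulationScenario",
    "GeneFixture",
    "simulate_gene_fixture",
    "simulate_reads",
    "scenario_from_table",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# gene fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFixtureConfig:
    """Shape of the synthetic target gene and its control.

    The target mimics a D2-receptor-like gene: ``n_exons`` exons with a
    short cassette exon at 0-based index ``cassette_index`` ("exon 6" when
    ``n_exons=7, cassette_index=5``), flanked by introns of the given
    phases.  ``cassette_codons=None`` draws uniformly from
    ``cassette_codon_range`` (24-33 codons).
    """

    n_exons: int = 7
    cassette_index: int = 5
    cassette_codons: int | None = None
    cassette_codon_range: tuple[int, int] = (24, 33)
    flank_phases: tuple[int, int] = (0, 0)
    exon_cds_range: tuple[int, int] = (90, 240)
    intron_range: tuple[int, int] = (80, 200)
    utr5: int = 30
    utr3: int = 50
    control_exons: int = 6
    include_control: bool = True


@dataclass
class GeneFixture:
    """Models, reference sequences, spliced transcripts and query metadata."""

    species_id: str
    models: dict[str, GeneModel]
    sequences: dict[str, str]
    isoforms: dict[str, IsoformModel]
    transcripts: dict[str, str]
    cassette_exon_id: str


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """An open reading frame of ``n_codons`` codons with no internal stop."""
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _partition_cds(
    rng: np.random.Generator, cfg: GeneFixtureConfig
) -> list[int]:
    """Per-exon CDS lengths realising the requested flanking intron phases."""
    ci = cfg.cassette_index
    if not 0 < ci < cfg.n_exons - 1:
        raise ValueError("cassette exon must be internal")
    lo, hi = cfg.exon_cds_range
    lens = list(rng.integers(lo, hi + 1, size=cfg.n_exons))
    codons = cfg.cassette_codons
    if codons is None:
        codons = int(rng.integers(*cfg.cassette_codon_range, endpoint=True))
    if codons < 1:
        raise ValueError("cassette exon must be at least one codon")
    p_up, p_dn = cfg.flank_phases
    # upstream intron phase = sum of CDS before the cassette, mod 3
    pre = sum(lens[:ci])
    lens[ci - 1] += (p_up - pre) % 3
    # cassette length sets the downstream phase
    lens[ci] = 3 * codons + ((p_dn - p_up) % 3)
    # total CDS must close the reading frame (incl. the stop codon)
    total = sum(lens)
    lens[-1] += (-total) % 3
    return [int(x) for x in lens]


def _assemble_gene(
    gene_id: str,
    species_id: str,
    seqid: str,
    rng: np.random.Generator,
    cds_lens: Sequence[int],
    intron_range: tuple[int, int],
    utr5: int,
    utr3: int,
) -> tuple[GeneModel, str]:
    """Lay a gene with the given per-exon CDS lengths onto a fresh sequence."""
    n_codons = sum(cds_lens) // 3 - 1
    cds = "ATG" + _random_cds(rng, n_codons - 1) + "TAA"
    assert len(cds) == sum(cds_lens)
    exon_seqs = []
    pos = 0
    for i, L in enumerate(cds_lens):
        chunk = cds[pos:pos + L]
        pos += L
        if i == 0:
            chunk = _random_seq(rng, utr5) + chunk
        if i == len(cds_lens) - 1:
            chunk = chunk + _random_seq(rng, utr3)
        exon_seqs.append(chunk)

    parts = [_random_seq(rng, 60)]  # upstream intergenic
    coords = []
    cursor = 60
    for i, es in enumerate(exon_seqs):
        coords.append((f"{gene_id}.e{i + 1}", cursor, cursor + len(es)))
        parts.append(es)
        cursor += len(es)
        if i < len(exon_seqs) - 1:
            ilen = int(rng.integers(*intron_range, endpoint=True))
            parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            cursor += ilen
    parts.append(_random_seq(rng, 60))
    genome = "".join(parts)

    first = coords[0]
    last = coords[-1]
    cds_spans = [(s, e) for _, s, e in coords]
    cds_spans[0] = (first[1] + utr5, first[2])
    cds_spans[-1] = (last[1], last[2] - utr3)
    model = build_gene_model(
        gene_id=gene_id,
        species_id=species_id,
        seqid=seqid,
        strand="+",
        exon_coords=coords,
        cds_spans=cds_spans,
    )
    return model, genome


def simulate_gene_fixture(
    config: GeneFixtureConfig = GeneFixtureConfig(),
    seed: int = 0,
    species_id: str = "spX",
) -> GeneFixture:
    """Deterministic target + control gene fixture for one species."""
    rng = np.random.default_rng(seed)
    target_id = f"{species_id}_drd2"
    control_id = f"{species_id}_actb"

    cds_lens = _partition_cds(rng, config)
    target, target_chrom = _assemble_gene(
        target_id, species_id, f"{species_id}_chr1", rng, cds_lens,
        config.intron_range, config.utr5, config.utr3,
    )
    sequences = {f"{species_id}_chr1": target_chrom}
    models = {target_id: target}

    exon_ids = tuple(e.exon_id for e in target.exons)
    ci = config.cassette_index
    isoforms = {
        f"{target_id}_L": IsoformModel(
            f"{target_id}_L", target_id, exon_ids, "inclusion"
        ),
        f"{target_id}_S": IsoformModel(
            f"{target_id}_S", target_id,
            exon_ids[:ci] + exon_ids[ci + 1:], "skipping",
        ),
    }

    if config.include_control:
        lo, hi = config.exon_cds_range
        ctl_lens = list(rng.integers(lo, hi + 1, size=config.control_exons))
        ctl_lens[-1] += (-sum(ctl_lens)) % 3
        control, control_chrom = _assemble_gene(
            control_id, species_id, f"{species_id}_chr2", rng,
            [int(x) for x in ctl_lens],
            config.intron_range, config.utr5, config.utr3,
        )
        sequences[f"{species_id}_chr2"] = control_chrom
        models[control_id] = control
        isoforms[f"{control_id}_t"] = IsoformModel(
            f"{control_id}_t", control_id,
            tuple(e.exon_id for e in control.exons), "other",
        )

    from .gene_models import splice_transcript

    transcripts = {
        iso_id: splice_transcript(models[iso.gene_id], iso, sequences)
        for iso_id, iso in isoforms.items()
    }
    return GeneFixture(
        species_id=species_id,
        models=models,
        sequences=sequences,
        isoforms=isoforms,
        transcripts=transcripts,
        cassette_exon_id=target.exons[ci].exon_id,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

ARTIFACT_CATEGORIES = (
    "rearranged_same_gene",
    "chimeric_same_species",
    "chimeric_foreign",
    "vector_or_barcode",
    "unidentified_short",
)


@dataclass(frozen=True)
class SpeciesLibrarySpec:
    """One species' library: mixture, depth, error and artifact levels."""

    species_id: str
    pi_s: float = 0.3  # skipping fraction among target-gene transcripts
    n_reads: int = 5000
    read_length_mean: float = 108.0
    read_length_sd: float = 20.0
    error_rate: float = 0.005
    chimera_fraction: float = 0.03  # of junction-spanning (retrievable) reads
    control_fraction: float = 0.5  # fraction of the library from the control gene

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_s <= 1.0:
            raise ValueError("pi_s must lie in [0, 1]")
        if not 0.0 <= self.chimera_fraction <= 1.0:
            raise ValueError("chimera_fraction must lie in [0, 1]")


@dataclass
class SimulationScenario:
    """A multi-species study design: per-species libraries + shared pools."""

    seed: int
    species: list[SpeciesLibrarySpec]
    gene_config: GeneFixtureConfig = field(default_factory=GeneFixtureConfig)
    n_vectors: int = 2
    vector_length: int = 60
    n_foreign: int = 3
    foreign_length: int = 500

    def pools(self) -> tuple[dict[str, str], dict[str, str]]:
        """Deterministic vector and foreign-sequence pools."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 917]))
        vectors = {
            f"vector{i + 1}": _random_seq(rng, self.vector_length)
            for i in range(self.n_vectors)
        }
        foreign = {
            f"foreign{i + 1}": _random_seq(rng, self.foreign_length)
            for i in range(self.n_foreign)
        }
        return vectors, foreign

    def fixture_for(self, index: int) -> GeneFixture:
        spec = self.species[index]
        sub = np.random.SeedSequence([self.seed, 31, index])
        return simulate_gene_fixture(
            self.gene_config,
            seed=sub,
            species_id=spec.species_id,
        )


def _mutate(seq: str, rng: np.random.Generator, rate: float,
            protect: tuple[int, int] | None = None) -> str:
    """iid substitutions at ``rate``; positions in ``protect`` untouched."""
    if rate <= 0.0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    for p in pos:
        if protect and protect[0] <= p < protect[1]:
            continue
        old = chars[p]
        alt = "ACGT".replace(old, "") or "ACGT"
        chars[p] = alt[rng.integers(0, len(alt))]
    return "".join(chars)


def queried_boundaries(fixture: GeneFixture, cassette_index: int) -> dict[str, int]:
    """Transcript offset of the junction each designed query interrogates.

    Inclusion and skipping isoforms are both queried at the boundary after
    the exon upstream of the cassette; the control at its exon 3|4 boundary.
    """
    out: dict[str, int] = {}
    for iso_id, iso in fixture.isoforms.items():
        junctions = _junction_positions(fixture, iso_id)
        if iso.label in ("inclusion", "skipping"):
            out[iso_id] = junctions[cassette_index - 1][1]
        else:
            out[iso_id] = junctions[2][1]
    return out


def _junction_positions(fixture: GeneFixture, iso_id: str) -> list[tuple[str, int]]:
    """(junction name, transcript offset of the boundary) for an isoform."""
    iso = fixture.isoforms[iso_id]
    model = fixture.models[iso.gene_id]
    out = []
    pos = 0
    ids = list(iso.exon_ids)
    for a, b in zip(ids, ids[1:]):
        pos += model.exon(a).length
        out.append((f"{a}|{b}", pos))
    return out


def _anchored_fragment(
    rng: np.random.Generator, transcript: str, boundary: int, flank: int = 15,
    extra: tuple[int, int] = (20, 50),
) -> str:
    """A transcript fragment containing the junction 30-mer plus clean flank."""
    lo = boundary - flank
    hi = boundary + flank
    a = int(rng.integers(*extra, endpoint=True))
    b = int(rng.integers(*extra, endpoint=True))
    return transcript[max(0, lo - a):min(len(transcript), hi + b)]


def _different_bases(template: str, rng: np.random.Generator) -> str:
    """A sequence mismatching ``template`` at every position."""
    out = []
    for ch in template:
        alt = "ACGT".replace(ch, "") if ch in "ACGT" else "ACGT"
        out.append(alt[rng.integers(0, len(alt))])
    return "".join(out)


def simulate_reads(
    scenario: SimulationScenario,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw every species' library; returns reads + a truth table.

    Non-artifact reads are uniform-start fragments of the isoform
    transcripts, with truncated-normal lengths and iid substitutions.
    Artifacts (five categories, uniform mix) are each built around an intact
    junction 30-mer so the counting stage retrieves them; their number is
    drawn so that the expected *retrieved* (junction-spanning) read set is a
    ``chimera_fraction`` artifact mixture, mirroring how chimera rates are
    observed — among the reads a junction query pulls back, not among the
    whole library.  Truth columns: read_id, species, isoform, category,
    length.
    """
    vectors, foreign = scenario.pools()
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    streams = np.random.SeedSequence([scenario.seed, 77]).spawn(
        len(scenario.species)
    )
    for si, spec in enumerate(scenario.species):
        fixture = scenario.fixture_for(si)
        rng = np.random.default_rng(streams[si])
        target = f"{fixture.species_id}_drd2"
        incl_id, skip_id = f"{target}_L", f"{target}_S"
        ctl_id = f"{fixture.species_id}_actb_t"
        if spec.pi_s > 0.0 and skip_id not in fixture.transcripts:
            raise ValueError(
                f"{spec.species_id}: pi_s > 0 but no skipping transcript"
            )
        boundaries = queried_boundaries(
            fixture, scenario.gene_config.cassette_index
        )
        n_control = rng.binomial(spec.n_reads, spec.control_fraction)
        n_target = spec.n_reads - n_control

        sources = [ctl_id] * n_control
        sources += [
            skip_id if u < spec.pi_s else incl_id
            for u in rng.random(n_target)
        ]
        n_span = 0  # clean reads whose fragment covers a queried 30-mer
        for ri, iso_id in enumerate(sources):
            t = fixture.transcripts[iso_id]
            L = int(np.clip(
                round(rng.normal(spec.read_length_mean, spec.read_length_sd)),
                30, len(t),
            ))
            start = int(rng.integers(0, len(t) - L + 1))
            b = boundaries[iso_id]
            if start <= b - 15 and start + L >= b + 15:
                n_span += 1
            seq = _mutate(t[start:start + L], rng, spec.error_rate)
            rid = f"{spec.species_id}_r{ri}"
            reads.append((rid, seq))
            truth_rows.append({
                "read_id": rid, "species": spec.species_id,
                "isoform": iso_id, "category": "clean", "length": L,
            })

        chi = spec.chimera_fraction
        n_chimera = (
            rng.binomial(n_span, chi / (1.0 - chi)) if chi < 1.0 else n_span
        )
        for ci in range(n_chimera):
            iso_id = skip_id if rng.random() < spec.pi_s else incl_id
            t = fixture.transcripts[iso_id]
            frag = _anchored_fragment(rng, t, boundaries[iso_id])
            cat = ARTIFACT_CATEGORIES[rng.integers(0, len(ARTIFACT_CATEGORIES))]
            if cat == "rearranged_same_gene":
                # strand-switch PCR artifact: append a distant region, RC'd
                w = 40
                far = int(rng.integers(0, max(1, len(t) - w)))
                seq = frag + reverse_complement(t[far:far + w])
            elif cat == "chimeric_same_species":
                other = fixture.transcripts[ctl_id]
                far = int(rng.integers(0, max(1, len(other) - 40)))
                seq = frag + other[far:far + 40]
            elif cat == "chimeric_foreign":
                pool = list(foreign.values())
                src = pool[rng.integers(0, len(pool))]
                far = int(rng.integers(0, max(1, len(src) - 40)))
                seq = frag + src[far:far + 40]
            elif cat == "vector_or_barcode":
                pool = list(vectors.values())
                src = pool[rng.integers(0, len(pool))]
                seq = frag + src[:40]
            else:  # unidentified_short: a short tail mismatching the template
                end = t.find(frag) + len(frag)
                template = t[end:end + 10]
                template = template + "A" * (10 - len(template))
                seq = frag + _different_bases(template, rng)
            rid = f"{spec.species_id}_c{ci}"
            reads.append((rid, seq))
            truth_rows.append({
                "read_id": rid, "species": spec.species_id,
                "isoform": iso_id, "category": cat, "length": len(seq),
            })
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "species", "isoform", "category", "length"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# study designs from a status table
# ---------------------------------------------------------------------------

DEPTH_TIERS = {"low": 5000, "medium": 8000, "high": 12000}


def scenario_from_table(
    table: pd.DataFrame,
    seed: int = 0,
    pi_s_when_present: float = 0.3,
    error_rate: float = 0.005,
    chimera_fraction: float = 0.03,
) -> SimulationScenario:
    """Scenario whose truth presence pattern equals a species status table.

    ``table`` columns: ``species`` (id), ``skipping`` (bool: short isoform
    expressed), ``depth_tier`` (low/medium/high).  Unknown tier keys are a
    hard error.
    """
    species = []
    for row in table.itertuples(index=False):
        tier = str(row.depth_tier)
        if tier not in DEPTH_TIERS:
            raise KeyError(f"unknown depth tier {tier!r} for {row.species}")
        species.append(SpeciesLibrarySpec(
            species_id=str(row.species),
            pi_s=pi_s_when_present if bool(row.skipping) else 0.0,
            n_reads=DEPTH_TIERS[tier],
            error_rate=error_rate,
            chimera_fraction=chimera_fraction,
        ))
    return SimulationScenario(seed=seed, species=species)


def write_fastq(reads: Sequence[tuple[str, str]], path: str) -> None:
    import gzip

    op = gzip.open if path.endswith(".gz") else open
    with op(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    import gzip

    op = gzip.open if path.endswith(".gz") else open
    out = []
    with op(path, "rt") as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h.strip().lstrip("@"), seq))
    return out
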