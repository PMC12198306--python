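import numpy as np
import pytest

from exonskip.gene_models import Exon, GeneModel, Intron, build_gene_model
from exonskip.simulate import GeneFixtureConfig, simulate_gene_fixture

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def toy_gene(cds_lens, gene_id="toy", strand="+", intron_len=50, seed=0,
             utr5=0, utr3=0):
    """A hand-laid plus-strand gene with the given per-exon CDS lengths.

    Returns (model, sequences).  Exon i is fully coding except for optional
    UTRs on the terminal exons.
    """
    rng = np.random.default_rng(seed)
    parts, coords, cds_spans = ["".join(random_seq(rng, 20))], [], []
    cursor = 20
    for i, L in enumerate(cds_lens):
        ex_len = L + (utr5 if i == 0 else 0) + (utr3 if i == len(cds_lens) - 1 else 0)
        coords.append((f"{gene_id}.e{i + 1}", cursor, cursor + ex_len))
        cs = cursor + (utr5 if i == 0 else 0)
        cds_spans.append((cs, cs + L))
        parts.append(random_seq(rng, ex_len))
        cursor += ex_len
        if i < len(cds_lens) - 1:
            parts.append("GT" + random_seq(rng, intron_len - 4) + "AG")
            cursor += intron_len
    parts.append(random_seq(rng, 20))
    chrom = "".join(parts)
    model = build_gene_model(gene_id, "toysp", "chrT", strand, coords, cds_spans)
    return model, {"chrT": chrom}


def bare_model(gene_id, cds_lens, phases):
    """A GeneModel skeleton (architecture only) for alignment-anchor tests."""
    exons, introns, pos = [], [], 0
    for i, L in enumerate(cds_lens):
        exons.append(Exon(f"{gene_id}.e{i + 1}", pos, pos + L, L))
        pos += L + 10
    for i, p in enumerate(phases):
        s = exons[i].end
        introns.append(Intron(f"{gene_id}.i{i + 1}", s, s + 10, p))
    return GeneModel(gene_id, "sp", "chr", "+", exons, introns)


@pytest.fixture(scope="session")
def fixture_gene():
    """Seeded target+control gene fixture shared across tests."""
    return simulate_gene_fixture(GeneFixtureConfig(), seed=11, species_id="spA")
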