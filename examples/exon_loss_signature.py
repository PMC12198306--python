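"""Detect exon deletion by recombination between flanking phase-0 introns.

A gene that keeps the cassette exon shows two phase-0 introns around it; a
gene that lost the exon genomically shows gapped alignment columns there
and a single phase-0 intron at the fused position.  This script builds both
architectures and runs the signature test.
"""

from exonskip.gene_models import Exon, GeneModel, Intron
from exonskip.intron_homology import detect_exon_loss_signature


def bare(gene_id, cds_lens, phases):
    exons, introns, pos = [], [], 0
    for i, L in enumerate(cds_lens):
        exons.append(Exon(f"{gene_id}.e{i + 1}", pos, pos + L, L))
        pos += L + 10
    for i, p in enumerate(phases):
        introns.append(Intron(f"{gene_id}.i{i + 1}", exons[i].end, exons[i].end + 10, p))
    return GeneModel(gene_id, "sp", "chr", "+", exons, introns)


# ancestral gene: 10 + 3 + 10 codons, cassette flanked by phase-0 introns
ancestral = bare("ancestral", (30, 9, 30), (0, 0))
prot_a = "MAAAAAAAAACCCDDDDDDDDDD"
# derived gene: cassette deleted, one fused phase-0 intron remains
derived = bare("derived", (30, 30), (0,))
alignment = [
    ("ancestral", prot_a),
    ("derived", prot_a[:10] + "---" + prot_a[13:]),
]

call = detect_exon_loss_signature(ancestral, derived, alignment, 0, 1)
print(f"cassette exon:  {call.cassette_exon_id}")
print(f"verdict:        {call.verdict}")
print(f"cassette columns {call.evidence['cassette_span_columns']}, "
      f"gap fraction in derived row: {call.evidence['gap_fraction_in_b']:.0%}")
print(f"phase-0 anchors: ancestral {len(call.evidence['anchors_a'])}, "
      f"derived {sum(1 for a in call.evidence['anchors_b'] if a.phase == 0)}")
# Two phase-0 anchors collapsing to one, with the exon's columns fully
# gapped, is the deletion-by-intron-recombination signature.
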