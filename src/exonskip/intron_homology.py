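"""Intron positions on protein alignments and the exon-deletion signature.

An intron's location can be expressed protein-side as an *alignment anchor*:
the alignment column of the residue immediately following the splice site,
plus the splice phase.  Two genes share a conserved intron when their anchors
agree in both column and phase — exact column agreement, no "intron sliding"
allowance by default.

A cassette exon flanked by two phase-0 introns leaves a characteristic
signature when it is deleted from the genome by recombination between those
introns: the gene that kept the exon shows two phase-0 anchors around it,
while in the other gene the exon's alignment columns are all gaps and a
single phase-0 anchor remains at the fused position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gene_models import GeneModel, NON_CODING_PHASE, translate_cds

__all__ = [
    "AlignmentAnchor",
    "ExonLossCall",
    "map_intron_to_alignment",
    "conserved_intron_pairs",
    "detect_exon_loss_signature",
    "read_alignment_fasta",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentAnchor:
    """An intron position expressed in alignment coordinates.

    ``column`` is the 0-based alignment column of the residue immediately
    following the intron (for phase 0 this is the first residue of the next
    exon, i.e. the anchor falls *between* residue columns); for phases 1-2 it
    is the column of the residue whose codon the intron splits.
    """

    row: int
    column: int
    phase: int
    intron_id: str = ""


@dataclass
class ExonLossCall:
    gene_a: str
    gene_b: str
    verdict: str  # retained | deleted_by_intron_recombination | no_signature
    cassette_exon_id: str = ""
    evidence: dict = field(default_factory=dict)


def read_alignment_fasta(path: str) -> list[tuple[str, str]]:
    """Aligned FASTA -> ordered [(name, row)] with uniform row width."""
    from Bio import SeqIO

    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    widths = {len(s) for _, s in rows}
    if len(widths) > 1:
        raise ValueError(f"ragged alignment in {path}: widths {sorted(widths)}")
    return rows


def _residue_columns(row_seq: str) -> list[int]:
    """Alignment column of each ungapped residue (in residue order)."""
    return [c for c, ch in enumerate(row_seq) if ch != GAP]


def map_intron_to_alignment(
    model: GeneModel,
    alignment: list[tuple[str, str]],
    row: int,
    protein: str | None = None,
) -> list[AlignmentAnchor]:
    """One anchor per coding intron of ``model`` on alignment row ``row``.

    When ``protein`` (the model's translated CDS) is given, the row's
    ungapped sequence must equal it; the first discordant residue is named
    otherwise.
    """
    row_seq = alignment[row][1]
    ungapped = row_seq.replace(GAP, "")
    if protein is not None and protein != ungapped:
        for i, (a, b) in enumerate(zip(protein, ungapped)):
            if a != b:
                raise ValueError(
                    f"row {row} ({alignment[row][0]}) disagrees with translated "
                    f"CDS of {model.gene_id} at residue {i + 1}: {a!r} vs {b!r}"
                )
        raise ValueError(
            f"row {row} ({alignment[row][0]}) and translated CDS of "
            f"{model.gene_id} differ in length"
        )

    cols = _residue_columns(row_seq)
    anchors = []
    upstream = 0
    for intron, exon in zip(model.introns, model.exons):
        upstream += exon.cds_len
        if intron.phase == NON_CODING_PHASE:
            continue
        phase = int(intron.phase)
        # residue index (0-based) of the residue following / containing the split
        res_idx = upstream // 3
        if res_idx >= len(cols):
            raise ValueError(
                f"intron {intron.intron_id} maps past end of row {row}"
            )
        anchors.append(
            AlignmentAnchor(
                row=row, column=cols[res_idx], phase=phase,
                intron_id=intron.intron_id,
            )
        )
    return anchors


def anchor_gene(
    model: GeneModel,
    cds: str,
    alignment: list[tuple[str, str]],
    row: int,
) -> list[AlignmentAnchor]:
    """Convenience wrapper validating the row against the translated CDS."""
    protein, _ = translate_cds(cds)
    return map_intron_to_alignment(model, alignment, row, protein=protein)


def conserved_intron_pairs(
    anchors_a: list[AlignmentAnchor],
    anchors_b: list[AlignmentAnchor],
    slack: int = 0,
) -> list[tuple[AlignmentAnchor, AlignmentAnchor]]:
    """Anchor pairs with identical phase and column (within ``slack``).

    Default ``slack=0`` demands exact column agreement; the result is
    symmetric in its arguments.
    """
    pairs = []
    for a in anchors_a:
        for b in anchors_b:
            if a.phase == b.phase and abs(a.column - b.column) <= slack:
                pairs.append((a, b))
    return pairs


def _exon_alignment_span(
    model: GeneModel, exon_index: int, row_seq: str
) -> tuple[int, int]:
    """Half-open alignment column span of one exon's residues on its row."""
    cols = _residue_columns(row_seq)
    up = sum(e.cds_len for e in model.exons[:exon_index])
    length = model.exons[exon_index].cds_len
    first = up // 3
    # round outward to whole residues
    last = (up + length + 2) // 3
    if last > len(cols):
        raise ValueError("exon maps past end of alignment row")
    return cols[first], cols[last - 1] + 1


def _cassette_candidates(model: GeneModel) -> list[int]:
    out = []
    for i in range(1, len(model.exons) - 1):
        if model.introns[i - 1].phase == 0 and model.introns[i].phase == 0:
            out.append(i)
    return out


def detect_exon_loss_signature(
    model_a: GeneModel,
    model_b: GeneModel,
    alignment: list[tuple[str, str]],
    row_a: int,
    row_b: int,
    anchors_a: list[AlignmentAnchor] | None = None,
    anchors_b: list[AlignmentAnchor] | None = None,
    cassette_exon_id: str | None = None,
    gap_fraction: float = 1.0,
) -> ExonLossCall:
    """Test whether ``model_b`` lost a phase-0-flanked exon of ``model_a``.

    Verdicts:

    * ``deleted_by_intron_recombination`` — the cassette exon's alignment
      columns are >= ``gap_fraction`` gapped in ``model_b``'s row, and where
      ``model_a`` shows the two flanking phase-0 anchors ``model_b`` shows
      exactly one phase-0 anchor at the fused position.
    * ``retained`` — the exon's columns are non-gap in both rows and both
      flanking anchors pair between the genes.
    * ``no_signature`` — anything else.
    """
    if row_a >= len(alignment) or row_b >= len(alignment):
        raise ValueError("alignment lacks a row for one of the genes")
    if anchors_a is None:
        anchors_a = map_intron_to_alignment(model_a, alignment, row_a)
    if anchors_b is None:
        anchors_b = map_intron_to_alignment(model_b, alignment, row_b)

    if cassette_exon_id is None:
        cands = _cassette_candidates(model_a)
        if len(cands) != 1:
            raise ValueError(
                f"{model_a.gene_id}: {len(cands)} phase-0/phase-0 flanked "
                "internal exons; pass cassette_exon_id explicitly"
            )
        ci = cands[0]
    else:
        ci = model_a.exon_index(cassette_exon_id)
        if ci == 0 or ci == len(model_a.exons) - 1:
            raise ValueError("cassette exon must be internal")

    exon = model_a.exons[ci]
    col_lo, col_hi = _exon_alignment_span(model_a, ci, alignment[row_a][1])
    b_row = alignment[row_b][1]
    span = b_row[col_lo:col_hi]
    gapped = span.count(GAP) / max(len(span), 1)

    up_id = model_a.introns[ci - 1].intron_id
    dn_id = model_a.introns[ci].intron_id
    flank_a = [x for x in anchors_a if x.intron_id in (up_id, dn_id)]
    flanks_phase0 = len(flank_a) == 2 and all(x.phase == 0 for x in flank_a)

    evidence = {
        "cassette_span_columns": (col_lo, col_hi),
        "gap_fraction_in_b": gapped,
        "anchors_a": flank_a,
        "anchors_b": anchors_b,
    }
    call = ExonLossCall(
        gene_a=model_a.gene_id, gene_b=model_b.gene_id,
        verdict="no_signature", cassette_exon_id=exon.exon_id,
        evidence=evidence,
    )
    if not flanks_phase0:
        return call

    # fused position: the downstream flank's column (first residue after the
    # deleted exon aligns there in both genes)
    fused_col = max(x.column for x in flank_a)
    b_phase0_at_fused = [
        x for x in anchors_b if x.phase == 0 and col_lo <= x.column <= fused_col
    ]

    if gapped >= gap_fraction:
        if len(b_phase0_at_fused) == 1:
            call.verdict = "deleted_by_intron_recombination"
        return call

    if gapped == 0.0:
        paired = conserved_intron_pairs(flank_a, anchors_b)
        if len({id(a) for a, _ in paired}) == 2:
            call.verdict = "retained"
    return call
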