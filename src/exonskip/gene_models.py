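"""Gene structures, intron phases, and isoform splicing.

A :class:`GeneModel` holds a gene's exon/intron architecture in *transcript
orientation* with 0-based half-open internal coordinates (GFF3's 1-based
inclusive coordinates are converted at the I/O boundary).  The central
quantity is each intron's *splice phase*: the number of coding nucleotides
upstream of the intron modulo 3.  A phase-0 intron splices between codons,
so a cassette exon flanked by two phase-0 introns can be skipped -- or
deleted outright from the genome -- without disrupting the reading frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "Exon",
    "Intron",
    "GeneModel",
    "IsoformModel",
    "NON_CODING_PHASE",
    "read_gene_models",
    "intron_phase",
    "splice_transcript",
    "translate_cds",
    "reverse_complement",
]

#: Sentinel phase for an intron that lies entirely within untranslated region.
NON_CODING_PHASE: str = "NC"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Exon:
    """One exon in transcript orientation.

    ``start``/``end`` are 0-based half-open genomic coordinates on the
    reference sequence; ``cds_len`` is the number of coding nucleotides the
    exon contributes.
    """

    exon_id: str
    start: int
    end: int
    cds_len: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    intron_id: str
    start: int
    end: int
    phase: int | str  # 0, 1, 2 or NON_CODING_PHASE


@dataclass
class GeneModel:
    """Exon/intron architecture of one gene on one reference sequence.

    Exons are ordered 5'->3' in transcript orientation; introns sit between
    consecutive exons.  ``cds_offset`` is the number of 5'-UTR nucleotides
    inside the first coding exon, measured along the spliced transcript.
    ``incomplete_orf`` flags a total CDS length not divisible by 3
    (possible pseudogene or partial annotation).
    """

    gene_id: str
    species_id: str
    seqid: str
    strand: str
    exons: list[Exon]
    introns: list[Intron] = field(default_factory=list)
    cds_offset: int = 0
    incomplete_orf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.introns) not in (0, max(len(self.exons) - 1, 0)):
            raise ValueError("introns must sit exactly between consecutive exons")

    # -- lookups ---------------------------------------------------------
    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(f"gene {self.gene_id} has no exon {exon_id!r}")

    def exon_index(self, exon_id: str) -> int:
        for i, e in enumerate(self.exons):
            if e.exon_id == exon_id:
                return i
        raise KeyError(f"gene {self.gene_id} has no exon {exon_id!r}")

    @property
    def cds_length(self) -> int:
        return sum(e.cds_len for e in self.exons)

    def coding_introns(self) -> list[Intron]:
        """Introns with a numeric phase (i.e. interrupting the CDS)."""
        return [i for i in self.introns if i.phase != NON_CODING_PHASE]

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneModel":
        d = json.loads(text)
        d["exons"] = [Exon(**e) for e in d["exons"]]
        d["introns"] = [Intron(**i) for i in d["introns"]]
        return cls(**d)


@dataclass(frozen=True)
class IsoformModel:
    """A splice isoform as an ordered subset of a gene's exons.

    ``label`` distinguishes the cassette-exon-including ('inclusion') and
    cassette-exon-skipping ('skipping') isoforms from anything else.
    """

    isoform_id: str
    gene_id: str
    exon_ids: tuple[str, ...]
    label: str = "other"

    def __post_init__(self) -> None:
        if self.label not in ("inclusion", "skipping", "other"):
            raise ValueError(f"unknown isoform label {self.label!r}")


# ---------------------------------------------------------------------------
# phase computation
# ---------------------------------------------------------------------------

def compute_intron_phases(exons: Sequence[Exon]) -> list[int | str]:
    """Phase of each intron from cumulative upstream CDS length mod 3.

    An intron whose upstream exons carry no CDS *and* whose downstream exons
    carry none either cannot interrupt the reading frame; those positions get
    :data:`NON_CODING_PHASE`.  An intron between two coding exons always has
    phase ``(upstream CDS) mod 3``.
    """
    phases: list[int | str] = []
    upstream = 0
    total = sum(e.cds_len for e in exons)
    for e in exons[:-1]:
        upstream += e.cds_len
        if upstream == 0 or upstream == total:
            # intron lies entirely in 5'- or 3'-UTR
            phases.append(NON_CODING_PHASE)
        else:
            phases.append(upstream % 3)
    return phases


def intron_phase(model: GeneModel, intron_index: int) -> int | str:
    """Splice phase of intron ``intron_index`` (0-based, transcript order)."""
    if not 0 <= intron_index < len(model.introns):
        raise IndexError(
            f"gene {model.gene_id} has {len(model.introns)} introns; "
            f"index {intron_index} out of range"
        )
    return model.introns[intron_index].phase


def build_gene_model(
    gene_id: str,
    species_id: str,
    seqid: str,
    strand: str,
    exon_coords: Sequence[tuple[str, int, int]],
    cds_spans: Sequence[tuple[int, int]],
) -> GeneModel:
    """Assemble a GeneModel from exon coordinates and CDS genomic spans.

    ``exon_coords`` are 0-based half-open genomic, in any order; they are
    sorted into transcript orientation here.  ``cds_spans`` are the genomic
    CDS segments; each exon's coding contribution is the overlap with them.
    """
    ordered = sorted(exon_coords, key=lambda t: t[1], reverse=(strand == "-"))
    exons = []
    for exon_id, start, end in ordered:
        if end <= start:
            raise ValueError(f"exon {exon_id} has non-positive length")
        cds_len = sum(
            max(0, min(end, ce) - max(start, cs)) for cs, ce in cds_spans
        )
        exons.append(Exon(exon_id, start, end, cds_len))
    for a, b in zip(exons, exons[1:]):
        lo, hi = (a.end, b.start) if strand == "+" else (b.end, a.start)
        if hi <= lo:
            raise ValueError(
                f"exons {a.exon_id}/{b.exon_id} of {gene_id} overlap or touch"
            )
    phases = compute_intron_phases(exons)
    introns = []
    for i, (a, b) in enumerate(zip(exons, exons[1:])):
        lo, hi = (a.end, b.start) if strand == "+" else (b.end, a.start)
        introns.append(Intron(f"{gene_id}.i{i + 1}", lo, hi, phases[i]))

    # 5'-UTR length inside the first coding exon
    cds_offset = 0
    for e in exons:
        if e.cds_len > 0:
            cds_offset = e.length - e.cds_len if _five_prime_utr_in(e, cds_spans, strand) else 0
            break
    total = sum(e.cds_len for e in exons)
    incomplete = total % 3 != 0
    if incomplete:
        warnings.warn(
            f"gene {gene_id}: CDS length {total} not divisible by 3 "
            "(possible pseudogene or partial model)",
            stacklevel=2,
        )
    return GeneModel(
        gene_id=gene_id,
        species_id=species_id,
        seqid=seqid,
        strand=strand,
        exons=exons,
        introns=introns,
        cds_offset=cds_offset,
        incomplete_orf=incomplete,
    )


def _five_prime_utr_in(exon: Exon, cds_spans: Sequence[tuple[int, int]], strand: str) -> bool:
    """Whether the non-coding part of the first coding exon is 5' of the CDS."""
    if not cds_spans:
        return False
    if strand == "+":
        cds_start = min(s for s, _ in cds_spans)
        return exon.start < cds_start
    cds_end = max(e for _, e in cds_spans)
    return exon.end > cds_end


# ---------------------------------------------------------------------------
# GFF3 + FASTA input
# ---------------------------------------------------------------------------

def read_gene_models(
    gff3_path: str,
    sequences: Mapping[str, str],
    species_id: str = "unknown",
) -> dict[str, GeneModel]:
    """Load gene models from a GFF3 annotation against reference sequences.

    Expects the conventional gene -> mRNA -> exon/CDS feature hierarchy; one
    mRNA per gene is assumed (the first is taken otherwise).  Minus-strand
    genes come back in transcript orientation.  An exon referencing an absent
    reference sequence is a hard error; a CDS length not divisible by 3 only
    flags the model.
    """
    import gffutils

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exon_coords = []
        for i, ex in enumerate(
            db.children(parent, featuretype="exon", order_by="start")
        ):
            exon_id = ex.attributes.get("ID", [f"{gene.id}.exon{i + 1}"])[0]
            # GFF3 1-based inclusive -> 0-based half-open
            exon_coords.append((exon_id, ex.start - 1, ex.end))
        cds_spans = [
            (c.start - 1, c.end)
            for c in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if gene.seqid not in sequences:
            raise KeyError(
                f"gene {gene.id} references absent sequence {gene.seqid!r}"
            )
        seq_len = len(sequences[gene.seqid])
        for _, s, e in exon_coords:
            if e > seq_len:
                raise ValueError(
                    f"exon of {gene.id} extends past end of {gene.seqid}"
                )
        models[gene.id] = build_gene_model(
            gene_id=gene.id,
            species_id=species_id,
            seqid=gene.seqid,
            strand=gene.strand,
            exon_coords=exon_coords,
            cds_spans=cds_spans,
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str) -> None:
    """Write models back out as GFF3 (gene/mRNA/exon/CDS rows)."""
    lines = ["##gff-version 3"]
    for m in models:
        gstart = min(e.start for e in m.exons)
        gend = max(e.end for e in m.exons)
        lines.append(
            f"{m.seqid}\texonskip\tgene\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        mrna_id = f"{m.gene_id}.t1"
        lines.append(
            f"{m.seqid}\texonskip\tmRNA\t{gstart + 1}\t{gend}\t.\t{m.strand}\t.\t"
            f"ID={mrna_id};Parent={m.gene_id}"
        )
        # CDS spans reconstructed from per-exon coding lengths
        for e in m.exons:
            lines.append(
                f"{m.seqid}\texonskip\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t"
                f"ID={e.exon_id};Parent={mrna_id}"
            )
        for cs, ce in _cds_spans_of(m):
            lines.append(
                f"{m.seqid}\texonskip\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t"
                f"ID={m.gene_id}.cds;Parent={mrna_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _cds_spans_of(m: GeneModel) -> list[tuple[int, int]]:
    spans = []
    first_coding_seen = False
    for e in m.exons:
        if e.cds_len == 0:
            continue
        utr = e.length - e.cds_len
        if not first_coding_seen:
            first_coding_seen = True
            if m.strand == "+":
                spans.append((e.start + utr, e.end))
            else:
                spans.append((e.start, e.end - utr))
        else:
            if m.strand == "+":
                spans.append((e.start, e.start + e.cds_len))
            else:
                spans.append((e.end - e.cds_len, e.end))
    return sorted(spans)


# ---------------------------------------------------------------------------
# splicing and translation
# ---------------------------------------------------------------------------

def exon_sequence(model: GeneModel, exon: Exon, sequences: Mapping[str, str]) -> str:
    raw = sequences[model.seqid][exon.start:exon.end].upper()
    return reverse_complement(raw) if model.strand == "-" else raw


def splice_transcript(
    model: GeneModel,
    isoform: IsoformModel,
    sequences: Mapping[str, str],
) -> str:
    """Concatenate the isoform's exon sequences in transcript orientation."""
    order = {e.exon_id: i for i, e in enumerate(model.exons)}
    idx = [order[x] for x in isoform.exon_ids]  # KeyError if absent
    if idx != sorted(idx):
        raise ValueError(
            f"isoform {isoform.isoform_id} lists exons out of gene order"
        )
    return "".join(
        exon_sequence(model, model.exons[i], sequences) for i in idx
    )


def translate_cds(
    seq: str, cds_offset: int = 0, cds_len: int | None = None
) -> tuple[str, bool]:
    """Translate from ``cds_offset`` with the standard code.

    Returns ``(protein, premature_stop)``: the protein up to the first stop
    codon, and a flag set iff that stop occurs before the final codon (the
    in-frame-stop pseudogene signature).  ``cds_len`` bounds the coding
    region so a trailing 3'-UTR is not mistaken for read-through sequence.
    Ambiguous codons become ``X``.
    """
    end = None if cds_len is None else cds_offset + cds_len
    cds = seq[cds_offset:end]
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    cds = cds[: len(cds) - len(cds) % 3]
    full = str(Seq(cds).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], stop < len(full) - 1


def translate_isoform(
    model: GeneModel,
    isoform: IsoformModel,
    sequences: Mapping[str, str],
) -> tuple[str, bool]:
    """Splice an isoform and translate exactly its coding portion."""
    t = splice_transcript(model, isoform, sequences)
    cds_len = sum(model.exon(x).cds_len for x in isoform.exon_ids)
    return translate_cds(t, model.cds_offset, cds_len)
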