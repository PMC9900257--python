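"""Gene models, canonical-transcript selection and coordinate mapping.

Transcript structures are read from GFF3 (gene/mRNA/exon/CDS with ``Parent``
links) and sequence from FASTA.  All coordinates are 1-based inclusive, the
GFF3 convention; nothing converts silently.  Mapping runs between three
spaces: genomic position, CDS position (1 = first coding base in the coding
orientation) and protein position (codon number).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pyfaidx
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: APPRIS labels ordered best-first; lower index = higher annotation quality.
APPRIS_ORDER = [
    "principal1", "principal2", "principal3", "principal4", "principal5",
    "alternative1", "alternative2",
]


class GeneNotFoundError(KeyError):
    """Requested gene symbol absent from the annotation."""


class MalformedModelError(ValueError):
    """Transcript structure violates a model invariant (names the transcript)."""


class AmbiguousCanonicalError(ValueError):
    """More than one transcript flagged as the MANE representative."""


class InternalStopWarning(UserWarning):
    """A CDS translates with a stop codon before the terminal codon."""


@dataclass(frozen=True)
class GenomicInterval:
    """Closed 1-based genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, gpos: int) -> bool:
        return self.start <= gpos <= self.end


@dataclass
class TranscriptModel:
    """One mRNA: exon/CDS intervals plus canonical-selection labels.

    ``exons`` and ``cds`` are kept in transcription order (exon 1 first:
    ascending genomic start on '+', descending on '-').
    """

    transcript_id: str
    gene_symbol: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    is_mane: bool = False
    appris_label: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise MalformedModelError(f"{self.transcript_id}: no exons")
        chroms = {iv.chrom for iv in self.exons + self.cds}
        strands = {iv.strand for iv in self.exons + self.cds}
        if len(chroms) != 1 or len(strands) != 1:
            raise MalformedModelError(
                f"{self.transcript_id}: intervals span multiple chrom/strand")
        by_start = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(by_start, by_start[1:]):
            if b.start <= a.end:
                raise MalformedModelError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise MalformedModelError(
                    f"{self.transcript_id}: CDS {c} not contained in an exon")
        if self.cds and self.cds_length % 3 != 0:
            raise MalformedModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(iv.start for iv in self.exons),
            max(iv.end for iv in self.exons),
            self.strand,
        )


@dataclass
class CodingSequence:
    """Spliced CDS read 5'->3' in coding orientation with per-base genomic map."""

    seq: str
    genomic_positions: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.genomic_positions):
            raise ValueError("seq and genomic_positions length mismatch")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"CDS length {len(self.seq)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def protein_length(self) -> int:
        """Number of amino acids excluding the terminal stop codon."""
        return len(self.seq) // 3 - 1


def read_label_tsv(path) -> dict[str, str]:
    """Read a two-column ``transcript_id<TAB>label`` TSV into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, label = line.split("\t")[:2]
            labels[tid] = label
    return labels


def _transcription_sort(intervals: list[GenomicInterval], strand: str) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: iv.start, reverse=(strand == "-"))


def load_gene_model(
    gff3_path,
    fasta_path,
    gene_symbol: str,
    mane_tsv=None,
    appris_tsv=None,
) -> list[TranscriptModel]:
    """Parse a GFF3 and return one :class:`TranscriptModel` per mRNA of a gene.

    ``mane_tsv``/``appris_tsv`` are optional two-column label tables
    (``transcript_id<TAB>label``) that localize the MANE and APPRIS
    annotations normally obtained from Ensembl.

    Raises :class:`GeneNotFoundError` if the symbol is absent and
    :class:`MalformedModelError` for structural defects.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = pyfaidx.Fasta(str(fasta_path))

    mane = read_label_tsv(mane_tsv) if mane_tsv else {}
    appris = read_label_tsv(appris_tsv) if appris_tsv else {}

    gene_feature = None
    for g in db.features_of_type("gene"):
        names = set(g.attributes.get("Name", [])) | set(
            g.attributes.get("gene_name", [])) | {g.id}
        if gene_symbol in names:
            gene_feature = g
            break
    if gene_feature is None:
        raise GeneNotFoundError(f"gene {gene_symbol!r} not found in {gff3_path}")

    models: list[TranscriptModel] = []
    for mrna in db.children(gene_feature, featuretype="mRNA", order_by="start"):
        if mrna.seqid not in fasta:
            raise MalformedModelError(
                f"{mrna.id}: contig {mrna.seqid!r} missing from FASTA")
        strand = mrna.strand
        exons = [
            GenomicInterval(f.seqid, f.start, f.end, strand)
            for f in db.children(mrna, featuretype="exon")
        ]
        cds = [
            GenomicInterval(f.seqid, f.start, f.end, strand)
            for f in db.children(mrna, featuretype="CDS")
        ]
        models.append(TranscriptModel(
            transcript_id=mrna.id,
            gene_symbol=gene_symbol,
            exons=_transcription_sort(exons, strand),
            cds=_transcription_sort(cds, strand),
            is_mane=mrna.id in mane,
            appris_label=appris.get(mrna.id),
        ))
    return models


def select_canonical(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Pick the canonical transcript: MANE first, then best APPRIS label.

    Remaining ties break deterministically by longest CDS, then
    lexicographically smallest transcript id.
    """
    if not transcripts:
        raise ValueError("select_canonical: empty transcript list")
    mane = [t for t in transcripts if t.is_mane]
    if len(mane) > 1:
        raise AmbiguousCanonicalError(
            "multiple MANE transcripts: "
            + ", ".join(t.transcript_id for t in mane))
    if len(mane) == 1:
        return mane[0]

    def rank(t: TranscriptModel):
        appris_rank = (
            APPRIS_ORDER.index(t.appris_label)
            if t.appris_label in APPRIS_ORDER else len(APPRIS_ORDER)
        )
        return (appris_rank, -t.cds_length, t.transcript_id)

    return min(transcripts, key=rank)


def extract_cds(
    t: TranscriptModel,
    genome,
    on_internal_stop: str = "warn",
) -> CodingSequence:
    """Splice the CDS from genomic sequence in coding orientation.

    ``genome`` is a :class:`pyfaidx.Fasta` or a FASTA path.  Minus-strand
    transcripts are reverse-complemented so ``seq`` reads 5'->3' in coding
    orientation; ``genomic_positions[i]`` is the genomic coordinate of base
    ``i``.  An internal stop codon warns by default
    (``on_internal_stop="error"`` raises).
    """
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))
    parts: list[str] = []
    positions: list[int] = []
    for iv in t.cds:  # already in transcription order
        piece = str(genome[iv.chrom][iv.start - 1: iv.end]).upper()
        if t.strand == "+":
            parts.append(piece)
            positions.extend(range(iv.start, iv.end + 1))
        else:
            parts.append(str(Seq(piece).reverse_complement()))
            positions.extend(range(iv.end, iv.start - 1, -1))
    seq = "".join(parts)
    cds = CodingSequence(seq=seq, genomic_positions=positions)

    protein = str(Seq(seq).translate())
    if not protein.endswith("*"):
        warnings.warn(
            f"{t.transcript_id}: CDS does not end in a stop codon",
            InternalStopWarning, stacklevel=2)
    internal = protein[:-1].find("*")
    if internal != -1:
        msg = (f"{t.transcript_id}: internal stop codon at protein "
               f"position {internal + 1}")
        if on_internal_stop == "error":
            raise MalformedModelError(msg)
        warnings.warn(msg, InternalStopWarning, stacklevel=2)
    return cds


def genomic_to_cds(t: TranscriptModel, gpos: int) -> int | None:
    """Map a genomic position to a 1-based CDS position.

    Returns ``None`` for intronic/UTR positions within the transcript span;
    positions outside the span raise ``ValueError``.
    """
    span = t.span
    if not span.contains(gpos):
        raise ValueError(
            f"position {gpos} outside transcript span "
            f"{span.chrom}:{span.start}-{span.end}")
    offset = 0
    for iv in t.cds:  # transcription order
        if iv.contains(gpos):
            within = gpos - iv.start if t.strand == "+" else iv.end - gpos
            return offset + within + 1
        offset += iv.length
    return None


def cds_to_protein(cds_pos: int) -> tuple[int, int]:
    """CDS position -> (amino-acid position, offset 1..3 within the codon)."""
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3, (cds_pos - 1) % 3 + 1


@dataclass
class LayoutSegment:
    """One drawn piece of the unspliced-transcript axis."""

    kind: str                 # "exon" | "intron"
    g_start: int              # genomic coordinates (g_start <= g_end)
    g_end: int
    x0: float                 # plot coordinates, x0 < x1, axis spans [0, 1]
    x1: float


@dataclass
class ExonLayout:
    """Exon-true / intron-compressed plot layout, exon 1 leftmost."""

    strand: str
    segments: list[LayoutSegment] = field(default_factory=list)

    def to_plot(self, gpos: int) -> float:
        """Map a genomic position to its plot coordinate (monotone in
        transcription order)."""
        for seg in self.segments:
            if seg.g_start <= gpos <= seg.g_end:
                if seg.g_end == seg.g_start:
                    frac = 0.5
                elif self.strand == "+":
                    frac = (gpos - seg.g_start) / (seg.g_end - seg.g_start)
                else:
                    frac = (seg.g_end - gpos) / (seg.g_end - seg.g_start)
                return seg.x0 + frac * (seg.x1 - seg.x0)
        raise ValueError(f"position {gpos} outside the gene span")

    @property
    def exon_segments(self) -> list[LayoutSegment]:
        return [s for s in self.segments if s.kind == "exon"]


def scale_exon_layout(t: TranscriptModel, intron_fraction: float = 0.2) -> ExonLayout:
    """Lay out the unspliced transcript on [0, 1], exon 1 leftmost.

    Exons keep their true relative scale within ``1 - intron_fraction`` of
    the axis; all introns are compressed to share ``intron_fraction``
    equally.  Minus-strand genes mirror onto the same left-to-right
    transcription order.
    """
    if not 0 <= intron_fraction < 1:
        raise ValueError("intron_fraction must be in [0, 1)")
    exons = t.exons  # transcription order
    n_introns = len(exons) - 1
    if n_introns == 0:
        intron_fraction = 0.0
    total_exon = sum(iv.length for iv in exons)
    exon_axis = 1.0 - intron_fraction
    intron_axis = intron_fraction / n_introns if n_introns else 0.0

    layout = ExonLayout(strand=t.strand)
    x = 0.0
    for i, exon in enumerate(exons):
        width = exon_axis * exon.length / total_exon
        layout.segments.append(LayoutSegment(
            "exon", exon.start, exon.end, x, x + width))
        x += width
        if i < n_introns:
            nxt = exons[i + 1]
            if t.strand == "+":
                g_start, g_end = exon.end + 1, nxt.start - 1
            else:
                g_start, g_end = nxt.end + 1, exon.start - 1
            layout.segments.append(LayoutSegment(
                "intron", g_start, g_end, x, x + intron_axis))
            x += intron_axis
    return layout
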