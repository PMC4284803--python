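"""Gene annotation model: intervals, transcripts, genes, biotypes.

Internal coordinates are 0-based half-open throughout; GTF's 1-based
inclusive convention is converted at the parsing/writing boundary so that
interval arithmetic is uniform with BED-style inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed or structurally inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Biotype(str, Enum):
    """Transcript categories used for the biotype distribution.

    Mirrors the classes distinguished in colorectal p53 transcriptome
    studies: protein-coding mRNA, the lncRNA subtypes (intergenic,
    antisense, sense-overlapping, sense-intronic), processed transcripts,
    pseudogene-derived and retained-intron transcripts, other small
    ncRNAs, and transcripts lacking any annotation (unassigned).
    """

    MRNA = "mRNA"
    LNC_INTERGENIC = "lnc_intergenic"
    LNC_ANTISENSE = "lnc_antisense"
    LNC_SENSE_OVERLAPPING = "lnc_sense_overlapping"
    LNC_SENSE_INTRONIC = "lnc_sense_intronic"
    PROCESSED_TRANSCRIPT = "processed_transcript"
    PSEUDOGENE = "pseudogene"
    RETAINED_INTRON = "retained_intron"
    OTHER_NCRNA = "other_ncRNA"
    UNASSIGNED = "unassigned"


#: Gencode tag -> Biotype. Unknown tags fall through to OTHER_NCRNA with a
#: warning; an empty tag means the transcript was never annotated.
GENCODE_BIOTYPE_MAP: dict[str, Biotype] = {
    "protein_coding": Biotype.MRNA,
    "lincRNA": Biotype.LNC_INTERGENIC,
    "lncRNA": Biotype.LNC_INTERGENIC,
    "antisense": Biotype.LNC_ANTISENSE,
    "antisense_RNA": Biotype.LNC_ANTISENSE,
    "sense_overlapping": Biotype.LNC_SENSE_OVERLAPPING,
    "sense_intronic": Biotype.LNC_SENSE_INTRONIC,
    "processed_transcript": Biotype.PROCESSED_TRANSCRIPT,
    "retained_intron": Biotype.RETAINED_INTRON,
    "pseudogene": Biotype.PSEUDOGENE,
    "processed_pseudogene": Biotype.PSEUDOGENE,
    "unprocessed_pseudogene": Biotype.PSEUDOGENE,
    "transcribed_processed_pseudogene": Biotype.PSEUDOGENE,
    "transcribed_unprocessed_pseudogene": Biotype.PSEUDOGENE,
    "unitary_pseudogene": Biotype.PSEUDOGENE,
    "polymorphic_pseudogene": Biotype.PSEUDOGENE,
    "miRNA": Biotype.OTHER_NCRNA,
    "snoRNA": Biotype.OTHER_NCRNA,
    "snRNA": Biotype.OTHER_NCRNA,
    "rRNA": Biotype.OTHER_NCRNA,
    "misc_RNA": Biotype.OTHER_NCRNA,
}

#: Canonical tag used when writing each Biotype back to GTF (inverse of the
#: mapping above, restricted to one representative per class).
BIOTYPE_TO_TAG: dict[Biotype, str] = {
    Biotype.MRNA: "protein_coding",
    Biotype.LNC_INTERGENIC: "lincRNA",
    Biotype.LNC_ANTISENSE: "antisense",
    Biotype.LNC_SENSE_OVERLAPPING: "sense_overlapping",
    Biotype.LNC_SENSE_INTRONIC: "sense_intronic",
    Biotype.PROCESSED_TRANSCRIPT: "processed_transcript",
    Biotype.PSEUDOGENE: "pseudogene",
    Biotype.RETAINED_INTRON: "retained_intron",
    Biotype.OTHER_NCRNA: "misc_RNA",
}

#: Biotype classes counted as lncRNA.
LNCRNA_BIOTYPES = frozenset(
    {
        Biotype.LNC_INTERGENIC,
        Biotype.LNC_ANTISENSE,
        Biotype.LNC_SENSE_OVERLAPPING,
        Biotype.LNC_SENSE_INTRONIC,
    }
)


def classify_biotype(raw_tag: str) -> Biotype:
    """Map a Gencode-style biotype string to the internal enumeration.

    An empty tag marks an unannotated transcript (``UNASSIGNED``); an
    unrecognized tag is logged and mapped to ``OTHER_NCRNA``.
    """
    if not raw_tag:
        return Biotype.UNASSIGNED
    try:
        return GENCODE_BIOTYPE_MAP[raw_tag]
    except KeyError:
        logger.warning("unknown biotype tag %r mapped to other_ncRNA", raw_tag)
        return Biotype.OTHER_NCRNA


@dataclass
class TranscriptModel:
    """A transcript: ordered exons on one chromosome/strand plus a biotype."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: Biotype = Biotype.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons span chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise AnnotationError(
                f"{self.transcript_id}: inconsistent exon strands {sorted(strands)}"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def three_prime_end(self) -> int:
        """Position of the last transcribed base (0-based)."""
        return self.end - 1 if self.strand != "-" else self.start


def tss(transcript: TranscriptModel) -> int:
    """Transcription start site: 5'-most transcribed base on the strand.

    First-exon start for '+' (and unstranded) transcripts, last-exon
    end − 1 for '−' transcripts.
    """
    if transcript.strand == "-":
        return transcript.end - 1
    return transcript.start


@dataclass
class GeneModel:
    """A gene locus grouping ≥1 transcripts; exposes one canonical TSS.

    The canonical TSS is the 5'-most transcript TSS on the gene strand,
    giving every gene a single unambiguous reference point for peak
    assignment (per-transcript assignment is available via
    :func:`p53lnc.peaks.annotate_peaks` with ``per_transcript=True``).
    """

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise AnnotationError(f"{self.gene_id}: transcripts span chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def canonical_tss(self) -> int:
        sites = [tss(t) for t in self.transcripts]
        return max(sites) if self.strand == "-" else min(sites)

    @property
    def biotype(self) -> Biotype:
        """Gene-level biotype: mRNA wins, then lncRNA subtypes, then rest."""
        order = list(Biotype)
        return min((t.biotype for t in self.transcripts), key=order.index)


# --- GTF I/O -----------------------------------------------------------

_BIOTYPE_ATTRS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype")


def parse_annotation(stream: Iterable[str] | IO[str]) -> list[TranscriptModel]:
    """Parse GTF exon features into transcript models.

    Accepts any iterable of GTF lines (Gencode attribute dialect:
    ``key "value";``). Coordinates are converted from 1-based inclusive
    to 0-based half-open. A transcript's biotype comes from the first of
    transcript_type/transcript_biotype/gene_type/gene_biotype present;
    absent tags leave the transcript unassigned.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    biotype_of: dict[str, Biotype] = {}
    order: list[str] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise AnnotationError(f"line {lineno}: cannot parse GTF line ({exc})")
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        try:
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(f"line {lineno}: exon lacks mandatory {exc} attribute")
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        if tid not in exons:
            exons[tid] = []
            order.append(tid)
            gene_of[tid] = gid
            raw = ""
            for key in _BIOTYPE_ATTRS:
                if key in attrs:
                    raw = attrs[key][0]
                    break
            biotype_of[tid] = classify_biotype(raw)
        exons[tid].append(iv)
    return [
        TranscriptModel(tid, gene_of[tid], exons[tid], biotype_of[tid])
        for tid in order
    ]


def write_annotation(transcripts: Iterable[TranscriptModel], handle: IO[str]) -> None:
    """Write transcripts as GTF exon lines (Gencode attribute dialect)."""
    for t in transcripts:
        tag = BIOTYPE_TO_TAG.get(t.biotype)
        for i, e in enumerate(t.exons, start=1):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if tag is not None:
                attrs += f' transcript_type "{tag}";'
            attrs += f' exon_number "{i}";'
            handle.write(
                f"{e.chrom}\tp53lnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{e.strand}\t.\t{attrs}\n"
            )


def build_genes(transcripts: Iterable[TranscriptModel]) -> dict[str, GeneModel]:
    """Group transcripts into gene models keyed by gene_id."""
    grouped: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        grouped.setdefault(t.gene_id, []).append(t)
    return {gid: GeneModel(gid, ts) for gid, ts in grouped.items()}


def biotype_distribution(transcripts: Iterable[TranscriptModel]) -> dict[str, int]:
    """Count transcripts per biotype (the annotation-summary table)."""
    counts = {b.value: 0 for b in Biotype}
    for t in transcripts:
        counts[t.biotype.value] += 1
    return counts
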