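"""Promoter evidence from active-chromatin histone marks.

A transcript 5' end is taken as genuinely promoter-driven when at least
one active mark (H3K4me3, H3K4me1 or H3K27ac) has a called region
overlapping the window ±5 kb around its TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomicInterval, TranscriptModel, tss
from .peaks import read_bed

PROMOTER_FLANK = 5_000  # bp either side of the TSS

ACTIVE_MARKS = ("H3K4me3", "H3K4me1", "H3K27ac")


@dataclass
class MarkTrack:
    """Called regions for one histone mark."""

    mark_name: str
    intervals: list[GenomicInterval]
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))
        self._trees = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    @classmethod
    def from_bed(cls, mark_name: str, path: str | Path | IO[str]) -> "MarkTrack":
        return cls(mark_name, read_bed(path))

    def max_overlap(self, chrom: str, start: int, end: int) -> int:
        """Largest bp overlap of any single region with [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        best = 0
        for hit in tree.overlap(start, end):
            best = max(best, min(hit.end, end) - max(hit.begin, start))
        return best


@dataclass(frozen=True)
class PromoterEvidence:
    transcript_id: str
    per_mark: dict[str, bool]
    active: bool


def promoter_mark_evidence(
    transcript: TranscriptModel,
    marks: Sequence[MarkTrack],
    flank: int = PROMOTER_FLANK,
    min_overlap: int = 1,
) -> PromoterEvidence:
    """Per-mark promoter support in the strand-agnostic window
    [TSS − flank, TSS + flank); active iff any mark overlaps by at least
    ``min_overlap`` bp."""
    site = tss(transcript)
    lo, hi = max(0, site - flank), site + flank
    per_mark = {
        m.mark_name: m.max_overlap(transcript.chrom, lo, hi) >= min_overlap
        for m in marks
    }
    return PromoterEvidence(transcript.transcript_id, per_mark, any(per_mark.values()))


def evidence_table(
    transcripts: Iterable[TranscriptModel],
    marks: Sequence[MarkTrack],
    flank: int = PROMOTER_FLANK,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Tabulate promoter evidence for a set of transcripts."""
    rows = []
    for t in transcripts:
        ev = promoter_mark_evidence(t, marks, flank, min_overlap)
        row = {"transcript_id": ev.transcript_id, **ev.per_mark, "active": ev.active}
        rows.append(row)
    return pd.DataFrame(rows)
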