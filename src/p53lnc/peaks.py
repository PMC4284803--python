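"""Peak-to-TSS annotation, positional histograms and metagene profiles.

A binding peak is assigned to the gene whose canonical TSS is closest to
the peak's reference point (the called summit when available, else the
interval midpoint). Distances are signed in the direction of
transcription: positive = downstream of the TSS. Peaks within 10 kb of
the nearest TSS (inclusive) are "proximal", the rest "distal".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

PROXIMAL_THRESHOLD = 10_000  # bp, inclusive


@dataclass(frozen=True)
class Peak:
    """A called binding interval with optional summit and signal score."""

    interval: GenomicInterval
    summit_offset: int | None = None
    signal: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.signal < 0:
            raise ValueError("peak signal must be nonnegative")

    @property
    def reference_point(self) -> int:
        """Summit position if called, else the interval midpoint (floor)."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    nearest_gene_id: str | None
    signed_distance: int | None
    klass: str  # "proximal" | "distal"


@dataclass
class ProfileMatrix:
    """Mean signal on a strand-oriented bp grid around a set of anchors."""

    offsets: np.ndarray  # bin start offsets relative to the anchor
    values: np.ndarray  # mean signal per bin across anchors
    n_anchors: int
    n_truncated: int = 0

    def __post_init__(self) -> None:
        assert len(self.offsets) == len(self.values)


class DistanceUndefinedError(ValueError):
    """Peak and gene lie on different chromosomes."""


def signed_tss_distance(peak: Peak, gene: GeneModel) -> int:
    """Orientation-aware distance from the gene's TSS to the peak point.

    Positive values are downstream of the TSS in the direction of
    transcription, negative upstream.
    """
    if peak.interval.chrom != gene.chrom:
        raise DistanceUndefinedError(
            f"peak on {peak.interval.chrom} vs gene {gene.gene_id} on {gene.chrom}"
        )
    point = peak.reference_point
    t = gene.canonical_tss
    return (t - point) if gene.strand == "-" else (point - t)


class _TssIndex:
    """Sorted per-chromosome TSS arrays for nearest-gene lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        per_chrom: dict[str, list[tuple[int, str, GeneModel]]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append((g.canonical_tss, g.gene_id, g))
        self._index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, entries in per_chrom.items():
            entries.sort(key=lambda e: (e[0], e[1]))
            pos = np.array([e[0] for e in entries], dtype=np.int64)
            self._index[chrom] = (pos, [e[2] for e in entries])

    def nearest(self, chrom: str, point: int) -> GeneModel | None:
        """Gene with minimal |TSS − point|; ties by lexicographic gene_id."""
        if chrom not in self._index:
            return None
        pos, genes = self._index[chrom]
        i = int(np.searchsorted(pos, point))
        candidates = [j for j in (i - 1, i, i + 1) if 0 <= j < len(pos)]
        best = min(
            candidates, key=lambda j: (abs(int(pos[j]) - point), genes[j].gene_id)
        )
        # equidistant anchors (same position, or mirrored around the point):
        # expand outward and break ties lexicographically by gene_id
        d0 = abs(int(pos[best]) - point)
        tied = []
        j = best
        while j >= 0 and abs(int(pos[j]) - point) == d0:
            tied.append(j)
            j -= 1
        lo = int(np.searchsorted(pos, point - d0, side="left"))
        hi = int(np.searchsorted(pos, point + d0, side="right"))
        for j in range(lo, hi):
            if abs(int(pos[j]) - point) == d0:
                tied.append(j)
        best = min(tied, key=lambda j: (genes[j].gene_id, j))
        return genes[best]


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    proximal_threshold: int = PROXIMAL_THRESHOLD,
    per_transcript: bool = False,
) -> list[PeakAnnotation]:
    """Assign each peak to its nearest gene and classify proximal/distal.

    The boundary |d| = ``proximal_threshold`` counts as proximal. A peak
    on a chromosome absent from the annotation is reported with a null
    gene and class distal (logged). With ``per_transcript=True`` every
    isoform TSS is a separate candidate anchor instead of one canonical
    TSS per gene (the reported id is still the gene id).
    """
    gene_iter = list(genes.values() if isinstance(genes, Mapping) else genes)
    if per_transcript:
        gene_iter = [
            GeneModel(g.gene_id, [t]) for g in gene_iter for t in g.transcripts
        ]
    index = _TssIndex(gene_iter)
    out: list[PeakAnnotation] = []
    for peak in peaks:
        gene = index.nearest(peak.interval.chrom, peak.reference_point)
        if gene is None:
            logger.warning(
                "peak %s on %s has no annotated chromosome; marked distal",
                peak.name or peak.interval,
                peak.interval.chrom,
            )
            out.append(PeakAnnotation(peak, None, None, "distal"))
            continue
        d = signed_tss_distance(peak, gene)
        klass = "proximal" if abs(d) <= proximal_threshold else "distal"
        out.append(PeakAnnotation(peak, gene.gene_id, d, klass))
    return out


def positional_histogram(
    annotations: Sequence[PeakAnnotation],
    bin_width: int,
    window: int,
    class_of_gene: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Histogram of signed TSS distances within ±``window``.

    Returns ``(bin_edges, counts_per_class)``. Bin edges run from
    −window to +window in steps of ``bin_width`` (which must divide
    2×window). Annotations with |d| ≤ window are counted; d = +window
    falls in the last bin. When ``class_of_gene`` is given, counts are
    stratified by the mapped class (unmapped genes land in "other"),
    otherwise a single "all" stratum is returned.
    """
    if (2 * window) % bin_width != 0:
        raise ValueError(f"bin width {bin_width} does not divide 2x window {window}")
    n_bins = (2 * window) // bin_width
    edges = np.arange(-window, window + bin_width, bin_width, dtype=np.int64)
    counts: dict[str, np.ndarray] = {}
    for ann in annotations:
        if ann.signed_distance is None or abs(ann.signed_distance) > window:
            continue
        if class_of_gene is None:
            key = "all"
        else:
            key = class_of_gene.get(ann.nearest_gene_id or "", "other")
        arr = counts.setdefault(key, np.zeros(n_bins, dtype=np.int64))
        b = min((ann.signed_distance + window) // bin_width, n_bins - 1)
        arr[b] += 1
    return edges, counts


# --- coverage track and metagene profile -------------------------------


class CoverageTrack:
    """Sparse per-base signal track (bedGraph semantics, missing = 0)."""

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # per chrom: (starts, ends, values), sorted, non-overlapping
        self._data = intervals

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CoverageTrack":
        data = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            data[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )
        return cls(data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); zero-filled, zero-padded
        outside the track's extent (start may be negative)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        starts, ends, vals = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            if a < b:
                out[a:b] = vals[i]
        return out

    def total_mass(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self._data.values())
        )


def metagene_profile(
    coverage: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    window: int,
    bin_width: int = 1,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Average strand-oriented signal around anchor positions (TSSs).

    For each anchor ``(chrom, pos, strand)`` the window
    [pos−window, pos+window) is extracted, reversed for '−' anchors so
    that positive offsets point downstream, averaged into bins of
    ``bin_width`` bp, then averaged across anchors. Windows running past
    a chromosome edge are zero-padded and counted in ``n_truncated``.
    """
    if not anchors:
        raise ValueError("metagene profile requires at least one anchor")
    if (2 * window) % bin_width != 0:
        raise ValueError("bin width must divide the window span")
    n_bins = (2 * window) // bin_width
    acc = np.zeros(n_bins, dtype=float)
    n_trunc = 0
    for chrom, pos, strand in anchors:
        # the anchor base itself maps to offset 0 on either strand
        lo, hi = (pos - window, pos + window) if strand != "-" else (
            pos - window + 1,
            pos + window + 1,
        )
        vals = coverage.values(chrom, lo, hi)
        truncated = lo < 0
        if chrom_sizes is not None and chrom in chrom_sizes:
            size = chrom_sizes[chrom]
            if hi > size:
                truncated = True
                excess = hi - size
                vals[len(vals) - excess :] = 0.0
        if truncated:
            n_trunc += 1
        if strand == "-":
            vals = vals[::-1]
        acc += vals.reshape(n_bins, bin_width).mean(axis=1)
    offsets = np.arange(-window, window, bin_width, dtype=np.int64)
    return ProfileMatrix(offsets, acc / len(anchors), len(anchors), n_trunc)


# --- interval overlap --------------------------------------------------


def interval_overlap_fraction(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> float:
    """Fraction of A intervals overlapping (≥1 bp) any B interval."""
    if not set_a:
        raise ValueError("overlap fraction undefined for empty query set")
    trees: dict[str, IntervalTree] = {}
    for iv in set_b:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    n_hit = sum(
        1
        for iv in set_a
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    )
    return n_hit / len(set_a)


# --- file I/O ----------------------------------------------------------


def read_bed(path: str | Path | IO[str]) -> list[GenomicInterval]:
    """Read intervals from a BED file (first 3–6 columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def read_narrowpeak(path: str | Path | IO[str]) -> list[Peak]:
    """Read ENCODE narrowPeak: col 7 = signalValue, col 10 = summit offset
    from start (−1 means not called)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    peaks = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand)
        signal = float(row[6]) if len(row) > 6 else 0.0
        summit = None
        if len(row) > 9 and int(row[9]) >= 0:
            summit = int(row[9])
        name = str(row[3]) if len(row) > 3 else ""
        peaks.append(Peak(iv, summit, signal, name))
    return peaks


def read_bedgraph(path: str | Path | IO[str]) -> CoverageTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return CoverageTrack.from_dataframe(df)


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Tabulate peak annotations (peak, gene, distance, class)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "chrom": a.peak.interval.chrom,
                "start": a.peak.interval.start,
                "end": a.peak.interval.end,
                "peak_name": a.peak.name,
                "nearest_gene_id": a.nearest_gene_id or "",
                "signed_distance": a.signed_distance,
                "class": a.klass,
            }
        )
    return pd.DataFrame(rows)
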