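"""Direct-target calling, unassigned-transcript triage, conservation.

A gene is a direct target when at least one of its transcripts is
differentially expressed (p < alpha in at least one replicate) AND at
least one proximal binding peak (|distance to TSS| ≤ 10 kb) is assigned
to it. Unassigned transcripts are triaged into assembly artefacts,
novel lncRNAs or likely-coding transcripts by a deterministic cascade
over promoter-mark evidence, position relative to the nearest upstream
gene, and coding potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd
from scipy import stats

from .chromatin import PromoterEvidence
from .genome import Biotype, GeneModel, GenomicInterval, TranscriptModel
from .peaks import PeakAnnotation, interval_overlap_fraction

DE_ALPHA = 0.01  # per-replicate significance rule
RUN_THROUGH_GAP = 5_000  # bp: 5' end this close past an upstream 3' end
CODING_CUTOFF = 0.364


@dataclass(frozen=True)
class DERecord:
    replicate: str
    log2_fold_change: float
    p_value: float


@dataclass
class DEResult:
    transcript_id: str
    records: list[DERecord]
    direction: str  # "up" | "down" | "ns"
    found: bool = True  # False when absent from every table


@dataclass
class DirectTarget:
    gene_id: str
    biotype: Biotype
    transcript_ids: list[str]
    peak_names: list[str]
    direction: str
    direction_conflict: bool = False


@dataclass(frozen=True)
class ConservationResult:
    n_query_loci: int
    n_overlapping: int
    fraction: float


@dataclass(frozen=True)
class NeighborContext:
    """Relation of an unassigned transcript to the nearest upstream
    gene's 3' end on the same strand: gap in bp from that 3' end to the
    transcript 5' end (None when no upstream gene exists)."""

    upstream_gene_id: str | None
    gap: int | None
    same_strand: bool


@dataclass(frozen=True)
class TriageVerdict:
    transcript_id: str
    verdict: str  # likely_artefact | novel_lncRNA | likely_coding
    reasons: tuple[str, ...]


def read_de_table(path: str | Path | IO[str], replicate: str = "") -> pd.DataFrame:
    """TSV with columns transcript_id, log2fc, p_value (and optionally
    replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "log2fc", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table lacks columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = replicate
    return df


def de_status(
    transcript_id: str,
    replicate_tables: Sequence[pd.DataFrame],
    alpha: float = DE_ALPHA,
) -> DEResult:
    """Differential-expression call: significant iff p < alpha in at
    least one replicate; direction from the most significant
    replicate's fold-change sign."""
    if not replicate_tables:
        raise ValueError("at least one replicate table is required")
    records: list[DERecord] = []
    for i, tab in enumerate(replicate_tables, start=1):
        rows = tab[tab["transcript_id"] == transcript_id]
        for row in rows.itertuples(index=False):
            rep = getattr(row, "replicate", "") or f"rep{i}"
            records.append(DERecord(str(rep), float(row.log2fc), float(row.p_value)))
    if not records:
        return DEResult(transcript_id, [], "ns", found=False)
    sig = [r for r in records if r.p_value < alpha]
    if not sig:
        return DEResult(transcript_id, records, "ns")
    best = min(sig, key=lambda r: r.p_value)
    direction = "up" if best.log2_fold_change > 0 else "down"
    return DEResult(transcript_id, records, direction)


def de_status_all(
    replicate_tables: Sequence[pd.DataFrame], alpha: float = DE_ALPHA
) -> dict[str, DEResult]:
    """Vectorised de_status over every transcript present in any table."""
    if not replicate_tables:
        raise ValueError("at least one replicate table is required")
    frames = []
    for i, tab in enumerate(replicate_tables, start=1):
        t = tab.copy()
        if "replicate" not in t.columns or (t["replicate"] == "").all():
            t["replicate"] = f"rep{i}"
        frames.append(t)
    allrows = pd.concat(frames, ignore_index=True)
    out: dict[str, DEResult] = {}
    for tid, grp in allrows.groupby("transcript_id", sort=False):
        records = [
            DERecord(str(r.replicate), float(r.log2fc), float(r.p_value))
            for r in grp.itertuples(index=False)
        ]
        sig = [r for r in records if r.p_value < alpha]
        if not sig:
            out[str(tid)] = DEResult(str(tid), records, "ns")
        else:
            best = min(sig, key=lambda r: r.p_value)
            out[str(tid)] = DEResult(
                str(tid), records, "up" if best.log2_fold_change > 0 else "down"
            )
    return out


def call_direct_targets(
    de_results: Mapping[str, DEResult],
    peak_annotations: Sequence[PeakAnnotation],
    genes: Mapping[str, GeneModel],
) -> list[DirectTarget]:
    """Intersect DE transcripts with proximal binding at the gene level.

    Returns targets sorted by gene_id. A gene with transcripts DE in
    conflicting directions reports the most significant transcript's
    direction and flags the conflict.
    """
    proximal_by_gene: dict[str, list[str]] = {}
    for ann in peak_annotations:
        if ann.klass == "proximal" and ann.nearest_gene_id is not None:
            proximal_by_gene.setdefault(ann.nearest_gene_id, []).append(
                ann.peak.name or f"{ann.peak.interval.chrom}:{ann.peak.interval.start}"
            )
    targets: list[DirectTarget] = []
    for gid in sorted(genes):
        if gid not in proximal_by_gene:
            continue
        gene = genes[gid]
        de_hits = [
            de_results[t.transcript_id]
            for t in gene.transcripts
            if t.transcript_id in de_results
            and de_results[t.transcript_id].direction != "ns"
        ]
        if not de_hits:
            continue
        best = min(
            de_hits, key=lambda d: min(r.p_value for r in d.records if r.p_value is not None)
        )
        directions = {d.direction for d in de_hits}
        targets.append(
            DirectTarget(
                gene_id=gid,
                biotype=gene.biotype,
                transcript_ids=sorted(d.transcript_id for d in de_hits),
                peak_names=sorted(proximal_by_gene[gid]),
                direction=best.direction,
                direction_conflict=len(directions) > 1,
            )
        )
    return targets


def target_biotype_counts(targets: Sequence[DirectTarget]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for t in targets:
        counts[t.biotype.value] = counts.get(t.biotype.value, 0) + 1
    return dict(sorted(counts.items()))


def triage_unassigned(
    transcript: TranscriptModel,
    evidence: PromoterEvidence,
    coding_prob: float | None,
    neighbor_context: NeighborContext,
    run_through_gap: int = RUN_THROUGH_GAP,
    coding_cutoff: float = CODING_CUTOFF,
) -> TriageVerdict:
    """Deterministic triage cascade for an unassigned transcript.

    1. likely_artefact — same-strand 5' end within ``run_through_gap``
       of an upstream gene's 3' end and no promoter marks (read-through
       / extended 3' UTR of the neighbour);
    2. likely_coding — coding probability at or above the cutoff;
    3. novel_lncRNA — promoter-active and sub-cutoff coding potential;
    4. likely_artefact — no promoter evidence.
    """
    if transcript.biotype != Biotype.UNASSIGNED:
        raise ValueError(f"{transcript.transcript_id} is not unassigned")
    if coding_prob is None:
        raise ValueError(
            f"{transcript.transcript_id}: coding probability is required for triage"
        )
    nc = neighbor_context
    if (
        nc.same_strand
        and nc.gap is not None
        and 0 <= nc.gap <= run_through_gap
        and not evidence.active
    ):
        return TriageVerdict(
            transcript.transcript_id,
            "likely_artefact",
            ("run_through_of_upstream_gene", "no_promoter_marks"),
        )
    if coding_prob >= coding_cutoff:
        return TriageVerdict(
            transcript.transcript_id, "likely_coding", ("coding_potential_above_cutoff",)
        )
    if evidence.active:
        return TriageVerdict(
            transcript.transcript_id,
            "novel_lncRNA",
            ("promoter_marks_present", "low_coding_potential"),
        )
    return TriageVerdict(
        transcript.transcript_id, "likely_artefact", ("no_promoter_evidence",)
    )


def neighbor_context_for(
    transcript: TranscriptModel, genes: Mapping[str, GeneModel]
) -> NeighborContext:
    """Nearest same-strand upstream gene whose 3' end precedes the
    transcript's 5' end in the direction of transcription."""
    from .genome import tss as _tss

    t5 = _tss(transcript)
    best_gid, best_gap = None, None
    for gid, g in genes.items():
        if g.chrom != transcript.chrom or g.strand != transcript.strand:
            continue
        if gid == transcript.gene_id:
            continue
        ends = [tr.three_prime_end() for tr in g.transcripts]
        if transcript.strand == "-":
            gaps = [e - t5 for e in ends if e >= t5]
        else:
            gaps = [t5 - e for e in ends if e <= t5]
        if gaps:
            gap = min(gaps)
            if best_gap is None or gap < best_gap or (gap == best_gap and gid < best_gid):
                best_gid, best_gap = gid, gap
    return NeighborContext(best_gid, best_gap, same_strand=best_gid is not None)


def conservation_fraction(
    query_loci: Sequence[GenomicInterval],
    mapped_other_species_peaks: Sequence[GenomicInterval],
) -> ConservationResult:
    """Fraction of query binding loci overlapped by peaks mapped in from
    another species (coordinates already lifted into the query
    assembly)."""
    if not query_loci:
        raise ValueError("conservation fraction undefined for an empty query set")
    frac = interval_overlap_fraction(query_loci, mapped_other_species_peaks)
    n_overlap = round(frac * len(query_loci))
    return ConservationResult(len(query_loci), n_overlap, frac)


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_in_universe: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X ≥ hits_in_set) for
    drawing ``set_size`` items from a universe containing
    ``hits_in_universe`` annotated items. Computed in log space by
    scipy's survival function."""
    if not (0 <= hits_in_set <= min(set_size, hits_in_universe)):
        raise ValueError("inconsistent hypergeometric counts")
    if set_size > universe_size or hits_in_universe > universe_size:
        raise ValueError("set or annotation larger than the universe")
    return float(
        stats.hypergeom.sf(hits_in_set - 1, universe_size, hits_in_universe, set_size)
    )


def targets_to_frame(targets: Sequence[DirectTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "biotype": t.biotype.value,
                "direction": t.direction,
                "direction_conflict": t.direction_conflict,
                "n_de_transcripts": len(t.transcript_ids),
                "n_proximal_peaks": len(t.peak_names),
                "transcript_ids": ",".join(t.transcript_ids),
                "peak_names": ",".join(t.peak_names),
            }
            for t in targets
        ]
    )
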