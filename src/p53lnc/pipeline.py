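"""End-to-end pipeline: annotation → peaks → triage → motifs → targets →
conservation → signature, with a JSON manifest of every output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatin import MarkTrack, evidence_table, promoter_mark_evidence
from .coding import (
    DEFAULT_CUTOFF,
    read_fasta,
    score_transcripts,
    train_coding_model,
)
from .genome import (
    Biotype,
    LNCRNA_BIOTYPES,
    biotype_distribution,
    build_genes,
    parse_annotation,
    tss,
)
from .motifs import motif_enrichment, p53re_scan
from .peaks import (
    PROXIMAL_THRESHOLD,
    annotate_peaks,
    annotations_to_frame,
    metagene_profile,
    positional_histogram,
    read_bedgraph,
    read_narrowpeak,
)
from .signature import AUC_CUTOFF, cluster_samples, crossval_signature, marker_statistics, read_ct_table
from .targets import (
    DE_ALPHA,
    call_direct_targets,
    conservation_fraction,
    de_status_all,
    neighbor_context_for,
    read_de_table,
    target_biotype_counts,
    targets_to_frame,
    triage_unassigned,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    annotation: str
    genome_fasta: str
    peaks: str
    output_dir: str
    de_tables: list[str] = field(default_factory=list)
    mark_beds: dict[str, str] = field(default_factory=dict)
    coverage: str | None = None
    cohort_ct: str | None = None
    cross_species_peaks: str | None = None
    alpha: float = DE_ALPHA
    proximal_threshold: int = PROXIMAL_THRESHOLD
    promoter_flank: int = 5_000
    coding_cutoff: float = DEFAULT_CUTOFF
    auc_cutoff: float = AUC_CUTOFF
    k_folds: int = 10
    seed: int = 0
    peak_window: int = 250  # half-width of sequence extracted around summits

    def validate(self) -> None:
        checks = {
            "alpha": 0 < self.alpha < 1,
            "proximal_threshold": self.proximal_threshold > 0,
            "promoter_flank": self.promoter_flank > 0,
            "coding_cutoff": 0 < self.coding_cutoff < 1,
            "auc_cutoff": 0 < self.auc_cutoff < 1,
            "k_folds": self.k_folds >= 2,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"configuration values out of range: {bad}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage in order and return the manifest.

    A stage failure raises :class:`StageError` naming the stage after
    writing a FAILED marker next to the partial outputs; optional stages
    (conservation, signature) run only when their inputs are given.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": [],
        "outputs": {},
        "summary": {},
    }
    stage = "setup"

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)

    try:
        # --- annotation ------------------------------------------------
        stage = "annotation"
        t0 = time.time()
        with open(config.annotation) as fh:
            transcripts = parse_annotation(fh)
        genes = build_genes(transcripts)
        dist = biotype_distribution(transcripts)
        emit(
            "biotype_distribution.tsv",
            pd.DataFrame(sorted(dist.items()), columns=["biotype", "n_transcripts"]),
        )
        manifest["summary"]["n_transcripts"] = len(transcripts)
        manifest["summary"]["n_genes"] = len(genes)
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # --- peak annotation -------------------------------------------
        stage = "peak_annotation"
        t0 = time.time()
        peaks = read_narrowpeak(config.peaks)
        annotations = annotate_peaks(peaks, genes, config.proximal_threshold)
        emit("peak_annotations.tsv", annotations_to_frame(annotations))
        n_prox = sum(1 for a in annotations if a.klass == "proximal")
        manifest["summary"]["n_peaks"] = len(peaks)
        manifest["summary"]["proximal_fraction"] = round(n_prox / max(len(peaks), 1), 4)
        class_of_gene = {
            gid: (
                "mRNA"
                if g.biotype == Biotype.MRNA
                else "lncRNA"
                if g.biotype in LNCRNA_BIOTYPES
                else "other"
            )
            for gid, g in genes.items()
        }
        edges, hist = positional_histogram(
            annotations, bin_width=1_000, window=config.proximal_threshold,
            class_of_gene=class_of_gene,
        )
        hist_df = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:]})
        for klass, counts in sorted(hist.items()):
            hist_df[klass] = counts
        emit("positional_histogram.tsv", hist_df)
        if config.coverage:
            track = read_bedgraph(config.coverage)
            anchors = [(g.chrom, g.canonical_tss, g.strand) for g in genes.values()]
            profile = metagene_profile(track, anchors, window=10_000, bin_width=100)
            emit(
                "metagene_profile.tsv",
                pd.DataFrame({"offset": profile.offsets, "mean_signal": profile.values}),
            )
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # --- chromatin evidence + coding potential + triage ------------
        stage = "triage"
        t0 = time.time()
        genome_seqs = read_fasta(config.genome_fasta)
        marks = [
            MarkTrack.from_bed(name, path) for name, path in sorted(config.mark_beds.items())
        ]
        ev_table = evidence_table(transcripts, marks, flank=config.promoter_flank)
        emit("promoter_evidence.tsv", ev_table)

        def spliced_seq(t) -> str:
            from .motifs import reverse_complement

            s = "".join(genome_seqs[t.chrom][e.start : e.end] for e in t.exons)
            return reverse_complement(s) if t.strand == "-" else s

        coding_like = [t for t in transcripts if t.biotype == Biotype.MRNA]
        noncoding_like = [t for t in transcripts if t.biotype in LNCRNA_BIOTYPES]
        triage_df = pd.DataFrame()
        unassigned = [t for t in transcripts if t.biotype == Biotype.UNASSIGNED]
        if coding_like and noncoding_like and unassigned:
            model, table = train_coding_model(
                [spliced_seq(t) for t in coding_like],
                [spliced_seq(t) for t in noncoding_like],
                cutoff=config.coding_cutoff,
            )
            scored = score_transcripts(
                {t.transcript_id: spliced_seq(t) for t in unassigned}, model, table
            )
            emit("coding_potential.tsv", scored)
            prob_of = dict(zip(scored["transcript_id"], scored["coding_prob"]))
            verdicts = []
            for t in unassigned:
                ev = promoter_mark_evidence(t, marks, flank=config.promoter_flank)
                ctx = neighbor_context_for(t, genes)
                v = triage_unassigned(
                    t, ev, prob_of[t.transcript_id], ctx,
                    coding_cutoff=config.coding_cutoff,
                )
                verdicts.append(
                    {
                        "transcript_id": v.transcript_id,
                        "verdict": v.verdict,
                        "reasons": ";".join(v.reasons),
                    }
                )
            triage_df = pd.DataFrame(verdicts)
            emit("triage.tsv", triage_df)
            manifest["summary"]["triage_counts"] = (
                triage_df["verdict"].value_counts().to_dict()
            )
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # --- motif enrichment ------------------------------------------
        stage = "motif_enrichment"
        t0 = time.time()
        rng = np.random.default_rng(config.seed)
        fore = []
        for p in peaks:
            centre = p.reference_point
            lo = max(0, centre - config.peak_window)
            hi = min(len(genome_seqs[p.interval.chrom]), centre + config.peak_window)
            fore.append(genome_seqs[p.interval.chrom][lo:hi])
        # length-matched background drawn uniformly from the genome
        back = []
        chrom_names = sorted(genome_seqs)
        for seq in fore:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            s = int(rng.integers(0, len(genome_seqs[chrom]) - len(seq)))
            back.append(genome_seqs[chrom][s : s + len(seq)])
        enrich = motif_enrichment(fore, back, p53re_scan, max_mismatch=2)
        manifest["summary"]["motif_enrichment"] = {
            "foreground_fraction": round(enrich.foreground_fraction, 4),
            "background_fraction": round(enrich.background_fraction, 4),
            "fold": enrich.fold if enrich.fold != float("inf") else "inf",
            "p_value": enrich.p_value,
        }
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # --- direct targets --------------------------------------------
        stage = "direct_targets"
        t0 = time.time()
        if config.de_tables:
            tables = [read_de_table(p) for p in config.de_tables]
            de = de_status_all(tables, alpha=config.alpha)
            targets = call_direct_targets(de, annotations, genes)
            emit("direct_targets.tsv", targets_to_frame(targets))
            manifest["summary"]["n_direct_targets"] = len(targets)
            manifest["summary"]["target_biotype_counts"] = target_biotype_counts(targets)
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # --- conservation (optional) -----------------------------------
        if config.cross_species_peaks:
            stage = "conservation"
            t0 = time.time()
            from .peaks import read_bed

            other = read_bed(config.cross_species_peaks)
            query = [p.interval for p in peaks]
            cons = conservation_fraction(query, other)
            manifest["summary"]["conservation"] = dataclasses.asdict(cons)
            manifest["stages"].append(
                {"stage": stage, "seconds": round(time.time() - t0, 2)}
            )

        # --- signature (optional) --------------------------------------
        if config.cohort_ct:
            stage = "signature"
            t0 = time.time()
            cohort = read_ct_table(config.cohort_ct)
            stats_df = marker_statistics(cohort, alpha=config.alpha)
            emit("marker_statistics.tsv", stats_df)
            result = crossval_signature(
                cohort, k=config.k_folds, seed=config.seed, auc_cutoff=config.auc_cutoff
            )
            emit(
                "cv_predictions.tsv",
                pd.DataFrame(
                    {"score": result.pooled_scores, "label": result.pooled_labels}
                ),
            )
            if result.selected:
                matrix = cohort.tissue_matrix("tumour")[result.selected].T
                row_order, col_order = cluster_samples(matrix)
                emit(
                    "clustering.tsv",
                    pd.DataFrame(
                        {"axis": ["markers"] * len(row_order) + ["patients"] * len(col_order),
                         "order": list(range(len(row_order))) + list(range(len(col_order))),
                         "item": row_order + col_order}
                    ),
                )
            manifest["summary"]["signature"] = {
                "per_marker_auc": {k: round(v, 4) for k, v in result.per_marker_auc.items()},
                "selected": result.selected,
                "pooled_cv_auc": round(result.pooled_auc, 4),
                "k": result.k,
                "seed": result.seed,
                "n_significant_markers": int(stats_df["significant"].sum()),
            }
            manifest["stages"].append(
                {"stage": stage, "seconds": round(time.time() - t0, 2)}
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"stage {stage} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
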