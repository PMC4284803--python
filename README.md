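# p53lnc

Integrative identification of **p53-regulated long noncoding RNAs** from
ChIP-seq binding peaks and differential-expression tables, plus
construction of a **tumour/normal qPCR biomarker signature** from those
lncRNAs. The package is aimed at regulatory-genomics analysts who have
peak calls, an annotation, DE tables, histone-mark tracks and a paired
qPCR cohort in hand, and want the downstream integration reproducible
and testable end to end (a bundled simulator generates all inputs with
planted ground truth).

## What it computes

**Binding → regulation.** Each binding peak is assigned to the gene with
the nearest transcription start site; the signed distance d (positive =
downstream in the direction of transcription) classifies the peak as
*proximal* (|d| ≤ 10 kb) or *distal*. A gene is a **direct target** when
at least one of its transcripts is differentially expressed (p < 0.01 in
≥1 of two replicates) *and* at least one proximal peak is assigned to
it. Bound regions are scanned for the dimeric p53 response element —
two RRRCWWGYYY half-sites with a 0–13 nt spacer — and its enrichment
over length-matched background is tested with a one-sided Fisher exact
test. Transcripts lacking any annotation are triaged into *assembly
artefact / novel lncRNA / likely coding* by a deterministic cascade over
promoter histone marks (H3K4me3 / H3K4me1 / H3K27ac in ±5 kb of the 5′
end), read-through geometry, and a CPAT-style coding-potential score
(longest-ORF length and coverage, Fickett TESTCODE statistic, hexamer
usage log-likelihood ratio, combined by logistic regression).

**Signature.** Marker expression is ΔCt = Ct(marker) − Ct(reference), so
higher ΔCt means lower expression. Per marker: a paired two-tailed
t-test on tumour−normal ΔCt, and a ROC curve with the tumour as the
positive class and ΔCt as score, AUC by the trapezoid rule (equal to the
tie-corrected concordance probability). Markers with AUC > 0.7 form the
signature; its joint accuracy is the pooled out-of-fold AUC of a
**tenfold patient-grouped cross-validated logistic regression** (fitted
by IRLS, no regularisation, with separation detection).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted truth:

```bash
python analysis/01_simulate_inputs.py    # genome, GTF, peaks, DE, marks, cohort
python analysis/02_annotate_peaks.py
python analysis/03_triage_unassigned.py
python analysis/04_motif_enrichment.py
python analysis/05_call_direct_targets.py
python analysis/06_signature.py
```

which prints, among other things:

```
90 peaks; 60 proximal (67%), 30 distal
45 unassigned transcripts triaged:  novel_lncRNA 24, likely_artefact 21
≤2 mismatches: foreground 0.48, background 0.09, fold 5.375, p = 3.15e-09
31 direct targets called; planted truth: 30; recovered 30, spurious 1
35 patients, 12 markers; 7 significantly shifted (paired t, P<0.01)
selected (AUC>0.7): ['lnc01', ..., 'lnc07']
tenfold pooled CV AUC = 0.987
```

Reading: two thirds of peaks are promoter-proximal; every one of the 30
planted direct targets is recovered and the single spurious call traces
to a null transcript whose uniform p-value dipped below 0.01 by chance;
the p53RE is ~5-fold enriched in bound sequence; and the planted
cohort shifts produce 7 significant markers of which those with AUC>0.7
classify tumour vs normal with pooled cross-validated AUC 0.99. Tables
land in `results/`, figures in `results/figures/`.

The same stages are available as subcommands of the `p53lnc` console
script (`simulate`, `annotate-peaks`, `cpat`, `scan-motif`, `signature`,
`run-all`), with `run-all` driving every stage from a YAML config and
writing a manifest with per-output checksums.

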