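# Methods

## Coordinate and annotation model

All internal coordinates are 0-based half-open; GTF's 1-based inclusive
convention is converted at the parse/write boundary so that interval
arithmetic is uniform with BED-family inputs. A transcript is an ordered
list of non-overlapping exons on one chromosome and strand; its TSS is
the 5′-most transcribed base (first-exon start on '+', last-exon end − 1
on '−'). A gene exposes one **canonical TSS**, the 5′-most transcript
TSS on the gene strand: peak assignment then has a single unambiguous
reference point per gene. Per-isoform assignment is available
(`annotate_peaks(..., per_transcript=True)`) because annotations differ
in isoform completeness; the gene-level mode is the default. Biotype
strings map through a fixed Gencode-style table; unknown tags are
warnings (annotations evolve), not errors, and an absent tag marks the
transcript *unassigned*.

## Peak annotation

The per-peak reference point is the called summit when present,
otherwise the interval midpoint (floor). The summit is the sharpest
available estimate of the binding position; the midpoint fallback keeps
plain BED input usable. Distances are signed in the direction of
transcription. The proximal/distal boundary is **inclusive at 10 kb**
(a peak exactly 10 kb from the TSS is proximal) and equidistant genes
are broken lexicographically by gene id, so annotation is a
deterministic function of its inputs. Coverage tracks are consumed as
bedGraph with absent bases read as zero; metagene profiles orient each
±10 kb window by strand before averaging, zero-pad windows that run off
a chromosome edge, and flag those anchors as truncated.

## Chromatin evidence

"Promoter-supported" is operationalised as ≥1 bp overlap between a
called mark region (H3K4me3, H3K4me1 or H3K27ac) and the strand-agnostic
window ±5 kb around the transcript 5′ end. The minimum overlap is
configurable (`min_overlap`); 1 bp is the default because called mark
regions are already thresholded upstream. The evidence is monotone in
the flank and invariant to splitting mark intervals.

## Coding potential

Four features per transcript sequence:

- **longest ORF** (nt, including the stop codon) over the three sense
  frames — transcripts are oriented, so the antisense strand is not
  scanned; codons containing N never match;
- **ORF coverage** = ORF length / transcript length;
- **Fickett TESTCODE** statistic from the classic published lookup
  tables (10 position-asymmetry bins with thresholds 1.9→1.1 and 10
  composition bins with thresholds 0.33→0.17, base-specific weights);
  values above ≈0.95 indicate coding, below ≈0.74 noncoding;
- **hexamer log-likelihood ratio**: mean log(coding/noncoding)
  probability over step-3 hexamers in the longest-ORF frame. The coding
  table is trained on in-frame (step-3) hexamers of coding training
  sequences, the noncoding table on all-frame (step-1) hexamers, each
  with pseudocount 1/4096 added before normalisation so every ratio is
  finite.

The features are combined by logistic regression (the same IRLS fit
used for the signature). The decision cutoff defaults to **0.364**, the
published human cutoff for this feature family; it is configurable and
echoed into output metadata. The package deliberately does not ship
pretrained weights: the model is trained per run on the annotated
mRNA vs lncRNA sets of the input annotation, which keeps the scorer
consistent with whatever genome it is applied to.

## p53 response-element scanning

Motif presence is established by scanning, not discovery. Two scanners:

- a PWM scanner (log-odds in bits against a uniform background unless
  one is supplied; N contributes zero; both strands, hits reported at
  forward coordinates);
- a consensus scanner for the dimeric element
  RRRCWWGYYY–N(s)–RRRCWWGYYY with s ∈ 0..13 and ≤2 mismatches over the
  20 informative positions (standard conventions for this element;
  both configurable). The dimeric pattern is palindromic under reverse
  complement (R↔Y, C↔G, W↔W with the site reversed), so a forward scan
  covers both strands and every genomic site is reported exactly once.

Enrichment compares per-sequence hit indicators between bound regions
(±250 bp around summits) and length-matched background with a one-sided
Fisher exact test; the fold is the ratio of hit fractions, reported as
infinite when the background fraction is zero.

## Direct targets and triage

A gene is a direct target iff ≥1 transcript is significant (p < alpha,
default 0.01, raw — no multiple-testing correction, matching the
replicate-supported convention; an FDR mode is available) in at least
one replicate table *and* ≥1 proximal peak is assigned to the gene. The
gene direction is the most significant transcript's fold-change sign;
conflicting transcript directions are flagged rather than silently
resolved.

Unassigned transcripts pass through a fixed cascade: (1) *artefact* if
the 5′ end lies ≤5 kb past an upstream same-strand gene's 3′ end and no
promoter mark supports it (read-through / extended 3′ UTR); (2) *likely
coding* if the coding probability reaches the cutoff; (3) *novel
lncRNA* if promoter-supported with sub-cutoff coding potential; (4)
otherwise *artefact* for lack of promoter evidence. The ordering puts
the strongest geometric artefact signal first and lets promoter marks
rescue read-through candidates; it is deterministic and partitions the
input.

Cross-species conservation is a plain overlap fraction of query binding
loci against peaks already mapped into the query assembly (coordinate
lifting is out of scope). Set enrichments use the upper-tail
hypergeometric probability computed through scipy's stable survival
function; tests cross-check it against exact integer PMF summation.

## Signature statistics

ΔCt = Ct(marker) − Ct(reference gene); ΔΔCt = ΔCt(tumour) −
ΔCt(normal); relative expression 2^−ΔΔCt (standard qPCR convention).
Missing wells stay NaN and are flagged, never imputed as zero. The
paired comparison is a two-tailed paired t-test; degenerate inputs are
defined explicitly (all differences zero → p = 1; constant nonzero
difference → p reported at the smallest positive float with a flag).

ROC curves sweep all distinct thresholds with the tumour as the
positive class and ΔCt as the score — tumours have *lower* expression,
hence *higher* ΔCt, so informative markers score AUC > 0.5. Tied scores
cross their threshold simultaneously (diagonal segments), which makes
the trapezoid area exactly the tie-corrected concordance
(concordant + ½·ties)/(n₁n₀); the suite asserts this identity to 1e−12.
Markers with AUC **strictly** greater than 0.7 are selected.

Logistic regression is maximum likelihood via IRLS, convergence on a
log-likelihood change < 1e−8, no regularisation by default. Complete
separation is detected two ways — a coefficient escaping ±30 during
iteration (the last finite iterate is kept; clipping would warp the
decision boundary) or the log-likelihood plateauing at 0 — and flags
the model rather than failing.

Cross-validation is tenfold, **patient-grouped**: both tissues of a
patient share a fold, which in this paired design also stratifies the
classes exactly. Fold assignment is a seeded permutation (the seed is a
mandatory input and echoed into all outputs). Out-of-fold predicted
probabilities are pooled into a single ROC/AUC rather than averaging
per-fold AUCs, which is the better-behaved estimator at 35 patients.
Heatmap ordering uses agglomerative clustering (Euclidean, average
linkage) with scipy's deterministic tie-breaking.

## Synthetic data

The generator emulates the study design, not its sequences: a
random-uniform genome (2 × 4.5 Mb by default) carrying 300 single-
transcript genes in a biotype mix echoing a polyadenylated cancer
transcriptome (55% mRNA, 17% lncRNA subtypes, 13% other noncoding, 15%
unassigned). Every mRNA gets a long ORF (~60% of its spliced length)
written into the genome so that coding-potential training sees genuine
signal. 40% of unassigned transcripts are re-positioned as monoexonic
read-through artefacts 0.2–5 kb past a host mRNA's 3′ end; mark
placement explicitly avoids their ±5 kb promoter windows so the triage
filter sees them unmarked, while host geometry guarantees genuine
promoters can still be marked. 30 planted direct targets receive a
literal dimeric p53RE (GGGCATGTCC ×2) written into the genome at a
strand-oriented offset drawn from an even mixture of N(0, 1.5 kb) and
N(−5 kb, 1.5 kb) — binding concentrated at the promoter and ~5 kb
upstream — plus one covering treated peak with a jittered summit; 60
decoy peaks (half near non-target TSSs, half in gene deserts) bring the
proximal fraction to ~⅔. The untreated peak set is a ~40% subset of the
treated one, emulating basal binding. DE tables: null transcripts have
p ~ U(0,1) and log2FC ~ N(0, 0.2); planted ones p ~ Beta(0.01, 1) and
|log2FC| ~ N(2, 0.5) with 75% induced, independently in two replicates.
A *noiseless* mode (planted p = 1e−6, null p ≥ 5α) exists for
truth-recovery checks where the model itself must not inject errors.

The paired cohort: per patient i and marker g, normal ΔCt = μ_g + u_i +
ε and tumour ΔCt = μ_g + δ_g + u_i + ε with patient effect u_i ~
N(0, τ²), noise ε ~ N(0, σ²), σ = 1, τ = 0.5, and per-marker shifts
δ = (2.5 ×5, 0.9 ×2, 0 ×5) across 35 patients — mirroring a panel of 12
assayed markers of which about 7 reach paired significance and 5–7
clear the AUC cutoff. Tables are emitted as raw Ct with a constant
reference Ct of 20, so the ΔCt reconstruction path is exercised.
Everything derives from one seed split into named substreams
(genome/peaks/expression/marks/cohort), making each stage independently
regenerable and every file byte-reproducible.

What the simulator does **not** model: realistic nucleotide
composition, read-level noise, isoform complexity, batch effects, or
mark signal strength. Passing tests therefore demonstrate the
*machinery* — coordinate handling, rule implementations, estimator
calibration — not performance on real tissue data.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (60–500 genes,
  0.9–7.5 Mb chromosomes, 10 000 null cohorts) were chosen as the
  smallest scales at which the checked distributional statements are
  sharp.
- The binormal closed form AUC = Φ(δ/(σ√2)) holds for two independent
  classes; the calibration check therefore runs the cohort generator
  with τ = 0 (a shared patient effect would shrink the pooled AUC
  below the closed form, by design of the paired model).
- Histogram bins are half-open with the single point d = +window folded
  into the last bin; bin width must divide the window span exactly.
- Equidistant-gene ties, triage rule order, clustering tie-breaks and
  CV fold assignment are all deterministic; two runs with equal
  seeds/configs produce byte-identical outputs and equal manifest
  checksums.

## Known limitations

- Gene-level DE aggregation trusts the transcript→gene mapping of the
  input annotation; a transcript assigned to the wrong gene propagates.
- The consensus p53RE scanner treats all 20 informative positions as
  equally weighted; affinity differences between half-site variants are
  only captured when a PWM is supplied.
- The triage cascade is a codified operationalisation of three evidence
  types; borderline transcripts (marked read-throughs, unmarked genuine
  promoters) inherit its rule order.
- ROC confidence intervals (DeLong/bootstrap) and external-cohort
  validation are out of scope.
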