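# Methods

## Overview

`mirspec` implements a four-stage discovery pipeline for cancer-specific
circulating miRNA biomarkers from paired tumor/normal miRNA-seq expression
matrices on the reads-per-million (RPM) scale, together with a synthetic
multi-cancer cohort generator that provides planted ground truth for every
stage.

## The fold-change statistic

For miRNA *i* and one cancer type, the tumor and normal expression vectors
are summarized by their *q*-quantile profiles. The *k*-th *q*-quantile of a
sample of size *N* is the linearly interpolated order statistic

    Q_k = x_h + (h − ⌊h⌋)(x_{h+1} − x_h),   h = (N − 1)(k/q) + 1,

with 1-based indexing on the sorted data and *h* clamped to [1, N]. With the
default q = 100 this yields the 99 percentiles of each group. The fold
change at quantile *k* is

    FC_ik = CQ_ik/NQ_ik − 1   if CQ_ik ≥ NQ_ik,
    FC_ik = 1 − NQ_ik/CQ_ik   otherwise,

which is antisymmetric under swapping the groups and zero exactly when the
two quantiles agree. RPM data contain zeros, and the formula divides by
either group's quantile; when either value falls below the pseudocount
(default 0.5 RPM) the pseudocount is added to both, preserving antisymmetry.
The original fold change OFC_i is the mean of the q − 1 values FC_ik (the
summation runs over quantile indices, not samples), and the improved fold
change weighs in the dispersion of the two quantile profiles:

    IFC_i = sign(OFC_i) · OFC_i² · σ_CQ / max(σ_NQ, ε)      (default)

where σ is the population standard deviation of a quantile profile and
ε = 1e-8 guards constant normal profiles. The printed source of this
statistic is typographically ambiguous, so two alternative readings are
selectable by configuration and kept auditable: `ofc_times_ratio`
(OFC·σ_CQ/σ_NQ) and `ofc_times_2sigmas` (OFC·2σ_CQσ_NQ). The default is the
most literal parse and keeps the statistic signed, which the downstream
selection rule (|IFC| > 0.5 on either side of zero) requires. All variants
preserve the sign of OFC. Quantiles are estimated on raw RPM, not
log-transformed values, matching the definition of the statistic on
expression values.

## Differential expression

Each miRNA is tested with a two-sided paired Wilcoxon signed-rank test over
patient-matched tumor/normal pairs. Zero differences are dropped; absolute
differences receive mid-ranks. For n ≤ 12 nonzero pairs the p-value is
exact by full enumeration of the 2^n sign assignments (well-defined under
rank ties); beyond that a normal approximation with tie and continuity
corrections is used — the two agree to < 0.02 at the switch point.
Benjamini–Hochberg correction is applied per cancer type (each cancer's
family of 500 tests adjusted separately). A miRNA is called differential
when |IFC| > 0.5 **and** q < 0.05, both strict. Up/down ratios in summary
tables are rounded half away from zero to three decimals (71/3 → 23.667).

Only patient-matched pairs enter the test: a signed-rank test is undefined
on unmatched samples, and tumors lacking a matched normal are dropped (and
counted by the input validator).

## Specificity

A differential miRNA of cancer C1 is *specific* to C1 when

    |IFC^{C1}| > t2   and   Σ_{j≠1} |IFC^{C1} − IFC^{Cj}| · δ^{Cj} > t1·t2·(k−1),

with defaults t1 = 0.75, t2 = 0.5, and k the number of cancer types in the
input (threshold 2.625 at k = 8). δ^{Cj} = 1 iff the miRNA's mean tumor
expression in C1 is at least its mean in Cj (inclusive), filtering
low-expression candidates. IFC^{Cj} is computed on cancer Cj's own
tumor/normal groups even where the miRNA is not differential there. The
candidate universe per target cancer is its differential set.

Two consequences worth noting. First, a genuinely down-regulated
cancer-specific miRNA has *lower* mean tumor expression in its target cancer
than anywhere else, so every δ term is zero and it can never pass — the
statistic is structurally oriented toward up-regulated (and
highly-expressed) markers. Second, because IFC grows with OFC², its
cross-cancer sampling variation is large for strong effects; miRNAs shifted
identically in every cancer are removed at only ~25–30% by the distance
criterion on synthetic data. We therefore quantify specificity false
positives as a rate over the full miRNA universe per target cancer (~9% at
the default conditions), not as a false-discovery proportion of the called
set.

## Biomarker panels

Specific, up-regulated miRNAs whose catalog source is plasma or serum are
candidate circulating biomarkers. All subsets of size 1..5 of the top
candidates (ranked by |IFC|, capped at `candidate_cap`, default 20, to bound
the exhaustive enumeration) are scored by two leave-one-out cross-validated
linear-discriminant accuracies:

* **accuracy 1** — tumor vs. paired normal samples of the target cancer, on
  the panel's RPM expression;
* **accuracy 2** — the target cancer's patient pairs vs. all other cancers'
  pairs, on per-pair fold-change profiles (the scalar fold-change formula
  applied to each pair's tumor/normal RPM values). Per-pair profiles are the
  construction consistent with the paired design; no per-sample fold change
  exists.

Panels are ranked by the mean of the two accuracies; ties break toward
smaller panels, then lexicographic miRNA ids, so reruns are identical. The
discriminant uses class means, a pooled within-class covariance with a ridge
term (default 1e-6; collinear panels stay well defined), and training-set
priors. Overall accuracy is (TP + TN)/N with every sample held out exactly
once; "randomly chosen" validation samples are traversed in arbitrary
(deterministic) order since all are used. LOOCV is computed by an exact
rank-one downdate of the class means and pooled scatter rather than
refitting, which is algebraically identical to the refit (tested) and makes
the exhaustive search O(N) per panel.

## The synthetic cohort generator

The generator emulates a TCGA-style paired collection: for each cancer type,
`n_pairs_per_type` patients contribute one tumor and one normal sample, all
labeled pathologic Stage I (the early-detection filter; the stage-filter
operation is exercised with mixed-stage fixtures in tests). Counts for
miRNA *i* in a sample of patient *p* are negative binomial with mean

    μ = L · a_i · u_{p,i} · e_{i,c,status},   Var = μ + φμ²,

where `a_i` is a log-normal relative abundance (σ = 1.5, heavy-tailed like
real miRNA libraries), `u_{p,i}` a per-patient log-normal profile factor
(σ = 0.3) shared between the patient's two samples — it survives RPM
normalization and is what a signed-rank test exploits — `L` the library
size (log-normal around `library_size_mean`), φ the NB overdispersion
(default 0.2), and `e` the planted effect: tumor samples of a differential
miRNA are scaled by 2^{±effect_log2fc}. Columns are then normalized to sum
to 10^6.

Planted structure: `frac_de` of the miRNAs are differential.
`frac_specific` of them are *cancer-specific* — assigned round-robin to
cancer types, shifted up in exactly that cancer. The remainder are
*background* differential miRNAs, shifted in every cancer with a common,
sign-balanced direction; they are differential everywhere but specific
nowhere, giving the specificity stage a true negative class. Two generator
design choices matter for interpretation:

* **Specifics are planted up-regulated.** The δ factor removes down-shifted
  specific targets by construction (above), so down-planted "truth" would be
  unrecoverable by the method under study; and the panel stage selects
  up-regulated circulating markers.
* **Differential miRNAs are drawn from the 30th–90th abundance-quantile
  band.** Planting a 4-fold shift into a library-dominating miRNA changes
  the RPM denominator for every other miRNA, turning the entire null set
  into apparent discoveries (OFC ≈ −1); planting into near-zero miRNAs makes
  the truth undetectable by any method. The band keeps the planted
  composition shift small relative to the signal.

The circulating catalog labels a configurable fraction (default 0.8) of the
planted specifics as plasma or serum — emulating partial coverage of a
curated extracellular-miRNA resource — assigns the rest non-blood sources
(exosome, Ago2, HDL), and adds a background sample of other differential
miRNAs with mixed labels.

Default conditions: 8 cancer types, 30 pairs per type, 500 miRNAs,
frac_de = 0.2, frac_specific = 0.08 (~5 specific miRNAs per cancer, the
scale of a 5-miRNA panel search), effect_log2fc = 2, dispersion 0.2,
library size 10^6. All randomness flows from a single integer seed; the same
seed reproduces the cohort bit for bit.

What the generator does **not** emulate: isomiR structure and arm
annotation, batch effects, unequal tumor/normal group sizes, cross-cancer
baseline heterogeneity (non-differential miRNAs have the same expected
expression in every cancer type), and real catalog curation noise. Passing
recovery tests therefore show that the implementation recovers the structure
the model plants under idealized conditions — not that the statistic ranks
real TCGA biomarkers correctly.

## Numerical choices

* Quantile index *h* clamped to [1, N]; degenerate inputs (N < 2, q < 2)
  are rejected.
* Pseudocount 0.5 RPM (configurable) in every fold-change ratio, applied
  symmetrically only when a value falls below it.
* σ floor 1e-8 in the IFC denominator.
* Wilcoxon: exact path for n ≤ 12 (capped at 24 to bound enumeration);
  continuity correction toward the mean in the approximation; miRNAs with
  all-zero differences are untestable and receive p = 1.
* Ratio rounding: decimal half-away-from-zero to 3 places; undefined (zero
  denominator) ratios are reported as `NA`, never a number.
* LDA ridge 1e-6; pooled covariance uses the two-class within-group scatter
  over N − 2 (N − 3 during LOOCV).
* All selection inequalities (|IFC| > 0.5, q < 0.05, the two specificity
  inequalities) are strict, as defined.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
default study conditions (500 miRNAs × 480 samples), 20 null cohorts of
500 miRNAs × 40 samples for calibration, and exhaustive oracle enumerations
at small n (quantiles N ≤ 8, sign enumeration n ≤ 10). A complete run of
the analysis scripts takes well under a minute on one CPU.

## Known limitations

* The specificity statistic is weakly discriminative for strong shared
  effects (see above); its false-positive behavior is reported over the
  miRNA universe.
* Exact Wilcoxon enumeration is exponential and hard-capped at n = 24.
* Accuracy 2 uses per-pair fold-change features; other constructions
  (aggregated per-cancer profiles) would give different panel rankings.
* The exhaustive panel search is bounded by `candidate_cap`; with more
  candidates than the cap, low-|IFC| candidates are never explored.
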