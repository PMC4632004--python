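# Methods

`stromamr` reimplements a systems-biology workflow for bulk tumor
expression cohorts, modeled on high-grade serous ovarian carcinoma
(HGS-OvCa): consensus molecular subtyping, quantification of stromal
admixture, reverse engineering of transcription-factor (TF) regulons,
master-regulator (MR) calling, and a three-group prognostic stratification
built from MR compound scores. This note documents the models, the
defaults and their rationale, what the synthetic cohorts do and do not
emulate, and the numerical choices that make results reproducible.

## The synthetic cohort model

Every analysis stage is exercised against cohorts with planted ground
truth generated by `stromamr.simulate`. A bulk sample is modeled on log2
scale as

    x_gs = b + (1 - f_s) * mE_gs + f_s * mS_gs + d_gs

where `b = 8` is a baseline, `f_s ∈ [0.05, 0.65]` is the sample's stromal
fraction, `mE` and `mS` are the mean expression profiles of the epithelial
(tumor-cell) and stromal populations, and `d` carries sample-to-sample
covariation.

* **Subtypes.** Four latent subtypes are drawn uniformly. Each contributes
  30 marker genes raised by 2.5 log2 units in `mE` (a strong
  subtype-defining metagene). The mesenchymal-like and
  immunoreactive-like subtypes draw `f` from the upper half of its range —
  stromal admixture is part of what defines them, which is the central
  phenomenon the pipeline is built to expose.
* **Stromal programs.** Two regulator programs are over-expressed in `mS`:
  a mesenchymal program (6 TFs) and an immunoreactive program (10 TFs),
  each TF with 20 targets. Per sample, a lineage weight (fibroblast-rich
  vs immune-rich stroma; base contrast 1.0/0.6/0.8 with jitter sd 0.10)
  and a per-regulon lognormal composition multiplier (cv 0.4, one cell
  population per regulon) scale the over-expression `shift = 2.0`.
* **Regulons.** The TF deviation is i.i.d. standard normal; each target's
  deviation is `mode * a * dev(TF) + sqrt(1 - a^2) * noise` with
  `a = 0.8` (the planted TF-target Pearson correlation) and 20% of modes
  repressive. Deviations enter at the bulk level, so the planted
  correlation is exact in the observed data. This is a deliberate model
  choice: mixing full profiles (means *and* variances) by `f` would make
  the stromal fraction modulate the variance of every stromal gene,
  coupling all of them through dispersion — a dependence that a mutual
  information estimator rightly detects but that swamps direct-edge
  recovery with indirect calls. The mean-mixture keeps admixture where it
  biologically matters for this pipeline (expression *levels*, hence
  ssGSEA scores, microdissection and xenograft contrasts) while leaving
  regulon covariation attributable to regulation. The cost is that pure
  profiles retain program covariation even at `f = 0`, which none of the
  planted-truth analyses rely on.
* **Survival.** Times are exponential with hazard
  `0.02 * exp(0.7 * z_mese - 0.5 * z_immu)` per month, where `z` are
  standardized per-sample signature means (median survival ≈ 35 months, a
  realistic figure for advanced disease); censoring is an independent
  exponential calibrated to a 30% censoring rate. The exponential
  proportional-hazards form is the simplest generator for which Cox
  recovery has known truth.
* **Paired designs** re-emit samples at altered stromal fractions:
  microdissection (f = 1 vs f = 0), patient-derived xenografts (native f
  vs f ≈ 0.02, human stroma replaced by mouse), and
  metastasis/chemotherapy (f shifted up by 0.15), each with fresh assay
  noise (sd 0.1).

**What the generator does not emulate:** probe- and batch-level microarray
artifacts, mouse-read contamination in PDX profiles, non-proportional
hazards, correlated censoring, and gene-level annotation noise. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under a clean admixture model, not robustness to
platform artifacts.

## Subtype discovery

NMF uses multiplicative (Frobenius) updates on min-shifted data (each gene
shifted by its minimum, preserving within-gene order), run to a relative
objective change below 1e-6 or 500 iterations, best of `n_restarts`
initializations; the objective is asserted non-increasing at every
iteration. Consensus clustering repeats NMF or k-means (k-means++ with 10
inner restarts) on 80% column subsamples; consensus entries are
co-clustering frequencies among co-sampled pairs; final labels come from
average-linkage clustering of `1 - consensus`, with the cophenetic
correlation reported for rank selection. Silhouette widths are computed on
`1 - consensus` (the natural dissimilarity at this stage); members of
singleton clusters get width 0; samples with non-positive width are
dropped as non-core.

A note on label extraction: with heavy stromal admixture the dominant
variance axis is stroma, and plain argmax-metagene NMF labels mix the two
stroma-rich subtypes (ARI plateaus near 0.8). This mirrors the real
observation that stromal content blurs subtype assignment. The consensus
k-means route resolves all four subtypes (ARI ≥ 0.85 on default cohorts);
plain NMF labeling reaches ARI 1.0 on high-purity, low-noise cohorts.

The differential statistic is a multiclass SAM-like score: a
between-class root-mean-square contrast divided by the pooled per-gene
standard error plus a fudge constant `s0` (median of the standard errors —
deterministic, in place of the percentile search). q-values follow the
median-count permutation recipe, clamped to [0, 1] and made monotone in
|d|. Genes at q < 0.05 feed a nearest-shrunken-centroid (PAM) classifier
with uniform class priors; the shrinkage Δ minimizes stratified
cross-validation error (5 folds; ties resolved toward the largest,
most parsimonious Δ). Each surviving gene is assigned to the class of its
largest positive shrunken deviation, giving disjoint per-subtype
up-regulated lists. Prediction requires ≥ 80% of classifier genes present.

## Enrichment scoring

GSEA operates on a supplied signed ranking with the weighted
Kolmogorov–Smirnov running sum (hit increments `|r|^p / Σ|r|^p`, miss
decrements `1/(N - Nh)`, ES = maximum deviation). Because the module
accepts a precomputed ranking rather than sample-level phenotypes, the
null is gene-label permutation (random member sets of matched size) —
a documented deviation from the phenotype-permutation default of
two-condition GSEA. p is the same-sign tail fraction, NES divides by the
mean same-sign |null ES|, and BH FDR is applied across the gene sets in a
call.

ssGSEA ranks genes within one sample (ties broken by stable gene order,
guaranteeing platform-independent determinism) and sums the difference
between the weighted in-set ECDF (member at descending position i weighted
`(N - i)^alpha`, `alpha = 0.25`, the method's canonical exponent) and the
uniform out-of-set ECDF. Scores are normalized per dataset by dividing by
`max - min` of the raw scores (the literal rule; a `minmax` variant that
also subtracts the minimum is a flag). Stromal/immune scores are ssGSEA
scores of the two signatures and the combined score is their sum.

## Network inference and master regulators

Mutual information uses equal-frequency binning of rank-transformed
vectors with `floor(n^(1/3))` bins (minimum 2) and the plug-in estimator
in nats. The estimator carries an O(bins²/n) positive bias; the
permutation null carries the same bias, so edge calls are bias-matched,
and the scalar entry point sums terms with exact (`fsum`) arithmetic so
MI(x, y) equals MI(y, x) bit-for-bit.

Per TF, MI is computed to every other gene; the null pools the MI of the
shuffled TF profile against all candidates across 100 permutations (one
shared null per TF — O(perms × genes), standard reverse-engineering
practice). BH correction is applied within each TF's tests; edges with
adjusted p < 0.05 survive, with mode = sign of the Spearman correlation.
Bootstrap filtering resamples samples with replacement and re-tests each
edge against the TF's original acceptance threshold (its smallest
significant MI); support below 0.6 (50 bootstraps) drops the edge. DPI
makes a single pass over all fully connected (TF, TF, target) triplets on
the frozen MI values, removing the strictly weakest edge (tolerance ε,
default 0).

MRA scores each regulon of ≥ 15 targets by the hypergeometric tail
P[X ≥ k] over the network's target universe, BH-corrected across TFs;
masters are calls at FDR < 0.05. Interaction modes are carried for
reporting but do not enter the overlap, and GSEA of the regulon against a
subtype differential ranking provides the orthogonal validation route.

## Prognosis

Compound scores are ssGSEA scores of the two MR sets (the packaged
signature is the 6 + 10 symbol lists in
`resources/mr_signature.gmt`). Activation is score strictly above the
within-dataset median (ties low — deterministic and conservative; under
independence the expected union/intersection activation fractions are
75%/25%). The two bits map to three groups: `immu+mese-`, `immu-mese+`,
and `mixed` (both or neither), with the `immu+mese+` / `immu-mese-`
subgroups retained for the both-active contrast. Meta-analysis normalizes
and dichotomizes within each cohort, then pools samples for a single
unstratified log-rank test and pooled KM curves (a cohort-stratified
variant was considered and left out of scope for the default path).
Kaplan–Meier, log-rank and univariate proportional-hazards fits (Efron
tie handling, Wald intervals) are delegated to lifelines. Paired score
comparisons use the Wilcoxon signed-rank test with zero differences
dropped (all-zero → p = 1 with a warning); unpaired use the rank-sum
test; all tests are two-sided, with BH across gene families.

## Calibration and problem sizes

The suite verifies, at the sizes given: log-rank type-I error within
0.05 ± 0.02 (2000 direct null replicates, n = 100); the full selection
pipeline (scores → median split → groups → log-rank) at nominal size
(1000–2000 null cohorts of 160 genes × 100 samples with both hazard
coefficients zero) — the guard against selection-induced inflation; Cox
Wald CI coverage ≈ 95% at n = 500 subjects (at n = 150 the interval
genuinely undercovers — z-statistic sd ≈ 1.07, coverage ≈ 0.93, identical
under an independent implementation — a finite-sample property of the
partial likelihood, so the larger size isolates the implementation from
the asymptotics); and recovery of a planted hazard ratio of 2 within
[1.8, 2.2] in ≥ 90% of replicates at n = 1000. Oracle equivalences
(hypergeometric tail vs exact enumeration at N ≤ 60, DPI vs an O(n³)
brute-force pruner, ssGSEA vs a literal double-loop ECDF) hold to
1e-12 or better. The reference cohort for parameter recovery is 550 genes
× 200 samples; sizes were chosen so the full suite runs in a few minutes
on one CPU.

## Known limitations

* The mean-mixture admixture model understates variance coupling present
  in real bulk mixtures; MI-network false-positive rates on real data will
  be higher than on these cohorts.
* Regulon inference assumes the TF's own transcript is informative for its
  activity; post-transcriptional regulation is not modeled.
* The silhouette filter operates on consensus dissimilarity, not
  expression distance; the two can disagree near cluster boundaries.
* Score normalization by `max - min` makes pooled scores sensitive to
  single outlier samples within a cohort; dichotomization is per-cohort,
  which shields the groups but not the normalized values.
* Survival modeling is univariate; clinical covariates, competing risks
  and time-varying effects are out of scope.
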