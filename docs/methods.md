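# Methods

## Scope and model chain

The package implements a candidate-SNP methylation analysis chain for
blood-methylation cohorts measured at two timepoints ("screening" and
"recall"): per-SNP epigenome-wide moderated linear models under a dominant
genetic coding, dual multiple-testing correction, empirical-null adjustment
of the test statistics, selection of CpGs consistently associated with
several SNPs at both timepoints, a windowed additive mQTL scan, and binary
phenotype / stress-CpG / transcript association models. A synthetic-cohort
generator with fully known ground truth drives all calibration and recovery
studies.

## Synthetic cohorts

Genotypes are drawn by a Gaussian copula: each of the two allele copies of
a variant is an indicator that a latent standard normal falls below
Φ⁻¹(MAF); latent variables within a chromosome block are equicorrelated
with parameter `ld_rho`. This yields Hardy–Weinberg marginals with the
configured MAF exactly, plus tunable LD. Defaults: six variants on chr7 at
MAFs 0.25/0.18/0.18/0.28/0.18/0.18, `ld_rho` = 0.3 (the candidate variants
are known to be in mutual LD; 0.3 gives moderate genotype correlation
without collinearity), n = 200 samples per timepoint and 2000 probes in a
~440 kb window — sizes chosen so one simulated scan is comparable to the
cohort sizes the design emulates while a 100-seed study stays cheap.

Methylation is generated on the M scale: per-probe baseline N(0, 2²), plus
planted additive/dominant SNP effects from the effect table, plus cell-type
effects (per-probe N(0, 0.5²) loadings on Dirichlet(6,4,2,2,4,22)
proportions — granulocyte-dominated blood), plus per-batch probe shifts
N(0, 0.1²) over two batches (58/42 split), plus N(0, 0.3²) noise. Betas are
the inverse-logit2 transform, hence strictly inside (0,1). Detection
p-values are below 5e-5 for passing entries; a per-entry failure fraction
(default 0.002) receives p > 0.01, injected uniformly at random because no
failure structure is specified for the emulated arrays. The default effect
table plants three cross-dependent CpGs (5%, 45%, 75% of the probe panel),
each receiving a dominant +0.8 M-unit effect from the two highest-MAF
variants — the effect size used throughout the planted-recovery studies;
the emulated studies report test statistics but no effect sizes, so this is
an artifact choice large enough to be detectable at n = 200 yet small on
the beta scale.

Phenotypes are Bernoulli draws through a logistic link on named predictors
(default: intercept −2, prevalence ≈ 12%, matching a low-prevalence
high-risk group); transcripts are linear in one probe's M value plus noise.
A single integer seed drives everything through crc32-keyed substreams
(one per stage), so identical configs are bit-identical across processes
while stages stay independently perturbable.

## Preprocessing

Sample filter: keep samples with detection p < 5e-5 in strictly more than
75% of probes. The sentence this rule derives from is ambiguous
("samples where more than 75% of samples…"); the implementation parallels
the probe rule, which matches common array practice. Probe filter: detected
(p < 0.01) in strictly more than 75% of samples. Annotation filter removes,
in order (first matching rule claims the probe): sex-chromosome probes,
non-CpG probes, probes with missing values, probes with an internal SNP of
MAF strictly above 5%, probes with a SNP at the CpG/single-base-extension
position, and cross-reactive probes from a supplied list.

Quantile normalization forces every sample onto the mean distribution of
order statistics; ties within a sample receive the average of their tied
target quantiles. Background/probe-type chemistry corrections (noob, BMIQ)
are out of scope: the simulator has no type I/II probe structure, and
quantile normalization alone equalizes the distributions the downstream
models see. Batch adjustment removes per-probe batch means (location), with
an optional scale step that squeezes per-batch variances toward their
across-probe average using the same moment-based empirical-Bayes machinery
as the variance moderation; the probe's grand mean is preserved to 1e-9.
Batch is additionally a model covariate downstream.

Cell composition: reference-based deconvolution solves, per sample,
min‖m − Rw‖₂ with w ≥ 0 and Σw ≤ 1 (SLSQP on the quadratic objective with
analytic gradient; K is small so the solver is exact to ~1e-8). Adjustment
regresses the K−1 free proportion columns (the last is determined by the
sum constraint) out of every probe, preserving the grand mean; constant or
collinear columns are dropped against an absolute tolerance because
proportions are O(1) and exactly-centered constants are otherwise kept by a
relative rank test.

All model fitting downstream uses M values; betas are for reporting.

## Discovery scan

Dominant coding is with respect to the minor allele, recomputed from the
data: if the alternate-allele frequency exceeds 0.5 the coding flips so
"minor allele present" is coded 1. Vectors constant after coding are
skipped as monomorphic. Missing genotypes propagate as NaN and the affected
samples are dropped per model with a logged count.

The moderated fit computes all per-probe OLS coefficients through one QR
decomposition (identical to per-probe OLS to machine precision; moderation
touches only variances). The variance prior (d₀, s₀²) comes from the
Fisher/digamma moment equations on log s²; when the excess variance of
log s² is non-positive, d₀ = ∞ and every posterior variance equals the
bias-corrected common scale exp(mean log s² + log(d/2) − ψ(d/2)). This
matches the reference empirical-Bayes implementation (limma) exactly,
including the degenerate case — note that with identical sample variances
the posterior is this common scale, not the raw s². Moderated two-sided
p-values use Student t with d₀+d df (normal when d₀ = ∞).

Multiple testing: BH step-up within each SNP scan, then multiplication by
the number of SNPs tested, clipped at 1 — the most literal reading of a
single "adjusted-for-SNP-count" column; re-running BH over the pooled
p-values is available as an alternative only through composing `bh_adjust`
on pooled input. Significance is snp-adjusted p < 0.05 throughout.

## Empirical null

A three-component Gaussian mixture (central null + left + right) is fitted
to the moderated t statistics by EM: initialization at the median/MAD with
side components at ±2 MAD, 10 jittered random restarts plus the base
initialization, best log-likelihood kept, convergence at Δloglik < 1e-8 or
500 iterations. Two numerical choices matter:

* side-component means are projected to stay at least 2 null-SDs from the
  null mean each iteration. Unpenalized ML on a *pure* Gaussian sample lets
  the side components absorb tail mass and biases the null SD down by
  ~2–3%; the separation constraint restores calibration (null SD 0.992 on
  10⁵ pure-null draws) while leaving contaminated-mixture recovery within
  ±0.05 (bias) and ±5% (inflation);
* after each restart the null is re-identified as the dominant component
  within 2 MAD of the median (falling back to the most central one), which
  keeps the estimator defined on small panels where strong signals can
  displace component 0.

This is a deterministic behavioral reimplementation of Gibbs-sampler-based
bias/inflation estimators, not a bit-exact one. Corrected statistics are
(t − μ₀)/σ₀ with two-sided normal p-values; FDR and SNP-count adjustment
are recomputed on the corrected p's.

## mQTL scan

Variant filters (all inclusive): rs-prefixed ID, info ≥ 0.9, A1 frequency
in [0.1, 0.9], position within the 1-based inclusive window (default: the
candidate gene ± 10 kb, chr7:1,845,430–2,282,580). The scan residualizes
methylation and allele dose on the covariates once and forms slopes from
cross-products; by Frisch–Waugh–Lovell this equals per-pair OLS (verified
to 1e-8 against a brute-force oracle), with df = n − p_cov − 1. FDR is BH
over all pairs of a scan; ranking tables can recompute BH per focus entity.
Partner ranking sorts by q ascending, |t| descending, partner ID — a total
order. Heatmap export emits position-ordered −log₁₀(p) and slope matrices
with NaN for skipped pairs.

## Phenotype models

Severity: severe iff the combined Freeman score (reversibility +
interruption, each 1–5) is strictly greater than 6, or the method was
violent, or the suicide was eventually completed. Risk bands: high iff the
band's nominal depression risk is ≥ ~50% (bands 4–5 of 0–5).

Logistic regression delegates to the IRLS fit in statsmodels (binomial
GLM, tol 1e-10); Wald z uses the inverse observed information with normal
reference (the convention of standard GLM summaries). Separation is an
explicit error (diverging |β| > 25, non-finite estimates, or the
underlying fitter's separation error), never silent output. CIs default to
Wald ± 1.96·SE for determinism; profile-likelihood CIs (bisection on the
profile deviance) are available behind `profile_ci=True` — published
intercept CIs of the emulated analyses are visibly asymmetric, so the two
conventions differ there by construction, while β/SE/z/p are unaffected.
Missing covariates: listwise deletion with logged counts. Ethnicity-style
factors should be treatment-coded with the most frequent level as
reference before entering the design.

The equal-variance t-test and Spearman correlation delegate to scipy;
CpG–CpG and transcript models are plain OLS with the cohort's covariates,
BH within cohort (CpG pairs) or across all pairs (transcripts). Direction
consistency: a pair is consistent iff all its nominally significant
(raw p < 0.05) per-cohort slopes share a sign; significance in a single
cohort is trivially consistent.

## Calibration studies and their problem sizes

The evaluation module regenerates every study from a seed: 100 null and
100 planted two-timepoint cohorts (2000 probes × 6 SNPs × 200 samples
each), empirical-null recovery on 20 000 draws of 0.95·N(0.3, 1.2²) +
0.05·N(4, 1), OLS-oracle agreement on 200-probe and 20×50-pair fixtures,
logistic CI coverage on 100 severity-style cohorts (n = 88, planted
methylation coefficient 1.5 on a centered M predictor), and deconvolution
recovery over 500 probes × 6 cell types at noise SD 0.02. The exhaustive
2×2-table logistic identity (β = ln(ad/bc)) is checked on a seeded random
sample of 100 tables with counts in 1–30 rather than all ~810 000, a
problem-size choice; the closed form leaves nothing structure-dependent
untested.

## What passing tests do and do not show

The generator reproduces the *structure* of array cohorts — LD blocks,
logit-normal methylation, cell and batch confounding, detection failures,
logistic phenotypes — but not array chemistry (type I/II probes, IDAT
intensities), imputation uncertainty (info scores are 1.0), fine-scale LD,
or realistic probe-annotation pathologies. Calibration results therefore
validate the statistical machinery and its implementation, not performance
on any particular real cohort; in particular the planted-recovery rates
reflect the chosen +0.8 M-unit effects at n = 200 and say nothing about
power for smaller real-world effects.

## Known limitations

* Quantile normalization attenuates per-probe cross-sample signal slightly
  on small panels; analyses that depend on the measurement-scale values
  (e.g. refitting a generated transcript coupling) should use the
  unnormalized M values.
* The empirical-null EM is a point estimator; no uncertainty on
  bias/inflation is propagated into the corrected p-values.
* The mQTL scan requires complete genotype vectors for the scanned
  variants (the discovery scan handles missing calls; the matrix scan does
  not).
* Profile CIs are computed coefficient-wise by refitting with an offset;
  for very large designs this is slow and Wald CIs are the default.
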