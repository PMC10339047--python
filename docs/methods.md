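# Methods

`metabomr` implements a two-arm screen of circulating metabolic measures
against incident non-alcoholic fatty liver disease (NAFLD): a prospective
observational arm (Cox proportional hazards on an ICD-10-derived incident
phenotype) and a genetic arm (two-sample Mendelian randomization from GWAS
summary statistics), joined by an effective-test multiplicity correction and
an explicit causal-call triage. Everything runs on synthetic data with known
ground truth; this note records the models, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not establish.

## Summary-statistic model and harmonization

A summary-statistic record is (variant, alleles, effect-allele frequency,
beta, SE, p, n), with beta per SD for continuous traits and log-odds for the
binary disease trait. Instruments are variants with p < 5e-8 (strict),
greedily LD-clumped: candidates sorted by ascending p (ties broken by chrom,
pos, variant id, so output is independent of row order), each retained
variant removing neighbours within 1 Mb whose r² exceeds 0.01. A named
region-exclusion preset covers the GCKR locus (chr2:27,219,709–28,246,554,
widened by 500 kb flanks), a strongly pleiotropic hepatic master regulator
that is routinely removed in metabolite MR as a sensitivity analysis.

Harmonization aligns outcome effects onto each exposure variant's effect
allele: swapped allele order negates the outcome beta, complementary-strand
codes are complemented first, and palindromic A/T and G/C variants are
aligned by allele-frequency concordance — dropped as ambiguous when either
trait's minor-allele frequency exceeds 0.42 (the common MR-software
convention; configurable). When an instrument is absent from the outcome a
proxy with r² strictly above 0.8 may substitute; the proxy's outcome effect
is re-signed by the LD correlation's sign and the original exposure record
is kept. Harmonizing an already-harmonized pair is a no-op (involution
safety, property-tested).

## Univariable MR

With per-variant ratios θ_j = β_Yj/β_Xj and first-order SEs se_Yj/|β_Xj|:

- **IVW (primary)** — weights w_j = β²_Xj/se²_Yj; the estimate equals WLS of
  β_Y on β_X through the origin. Multiplicative random effects: the fixed
  SE is inflated by √φ with φ = max(1, Q/(k−1)); flooring at 1 is the
  under-dispersion correction. Cochran's Q and φ are reported.
- **MR-Egger** — weighted regression with intercept after orienting every
  variant to β_X ≥ 0 (the intercept, the mean direct effect, is only
  interpretable under a fixed exposure-increasing orientation; this
  orientation convention is a design choice). SEs are
  scaled by max(1, √(RSS_w/(k−2))).
- **Weighted median** — interpolates the inverse-variance-weighted ratio
  distribution at probability ½; SE from a seeded parametric bootstrap
  (1000 resamples by default).
- **Contamination mixture** — per-variant likelihood is the larger of a
  valid term N(θ, se²_j) and an invalid term N(0, se²_j + ψ²), profiled over
  a θ grid (default: IVW ± 6 SE, step SE/10, widened until the maximum is
  interior; ψ = 1.5·SD of the ratios). The 95% region is the grid set
  within χ²₁(0.95)/2 of the maximum and may be a union of disjoint
  intervals; a likelihood-ratio test against θ = 0 supplies the p-value.
  Because the invalid component is centred at zero, symmetric-looking ratio
  clusters are not treated symmetrically unless ψ is large — the
  multimodality test constructs its fixture accordingly.
- **MR-PRESSO** — observed statistic: Σ_j of the se²_Y-standardized squared
  residual of β_Yj about its leave-one-out IVW prediction; the null comes
  from parametric simulation (β*_X ~ N(β̂_X, se²_X), β*_Y ~ N(θ̂₋ⱼβ̂_X,
  se²_Y)) with the same statistic recomputed per simulated dataset.
  Empirical p-values are floored at 1/(n_sim+1); per-variant outlier tests
  are Bonferroni-corrected across k, and the reported estimate is IVW on the
  unflagged variants. The distortion test is not implemented. Note the
  identifiability limit: with few instruments a gross outlier drags every
  leave-one-out prediction and neighbours get flagged collaterally; clean
  single-outlier attribution needs the outlier's weight share to be small
  (the tests use k = 50) and n_sim large enough that the corrected p floor
  k/(n_sim+1) sits below the test level.

Instrument strength: F_j = (β_Xj/se_Xj)², r²_j = t²/(t²+n−2), overall
F = r²(n−k−1)/((1−r²)k). Steiger filtering recovers |correlations| from
t-statistics, compares Fisher-z transforms between samples one-sidedly, and
removes variants explaining more outcome than exposure variance; for the
binary outcome the log-odds t-statistic is used directly (an approximation).
Reverse MR treats continuous liver fat — not the dichotomized disease — as
the exposure, since MR with a binary exposure of a continuous liability is
not recommended.

## Multivariable MR

MVMR re-estimates each exposure's direct effect with waist circumference as
a second exposure sharing the same instruments. MVMR-IVW is WLS of β_Y on
the k×p exposure-beta matrix through the origin (weights 1/se²_Y, SE scale
max(1, √(Q/(k−p)))); MVMR-Egger adds an intercept after orienting to the
primary exposure; the multivariable median minimizes the weighted sum of
absolute residuals (an exact LP, solved by HiGHS) with bootstrap SEs;
MVMR-Lasso gives each variant an L1-penalized direct-effect intercept,
solved by coordinate descent (tolerance 1e-8) over a descending log-spaced λ
grid, selecting the largest λ whose zero-intercept subset is homogeneous
(Q ≤ χ²₀.₉₅) and refitting IVW on that subset. Conditional instrument
strength for exposure e is the weighted residual sum of squares of
regressing its betas on the other exposures' betas, divided by k−p+1;
cross-exposure GWAS error covariances are set to zero — a documented
limitation when exposures share one GWAS sample.

## Observational arm

Incident cases are defined by first occurrence of K74.0, K74.2 (hepatic
fibrosis), K75.8 (NASH), K76.0 (NAFLD) or K76.9; any other K74/K75/K76 code
marks non-NAFLD liver disease and removes the participant; cases dated
before enrollment are excluded from the incident analysis. Cox models
(lifelines; Efron ties by default, Breslow by flag) use follow-up years from
enrollment as the time scale and report HR per SD for metabolites
standardized on the post-exclusion analysis sample. Kaplan–Meier curves are
product-limit estimates per group. Quintiles cut at the 20/40/60/80
percentiles with ties to the lower group. Metabolic dyslipidemia follows
NCEP-ATPIII: high TG means TG ≥ 1.7 mmol/L (boundary inclusive, the "≥150
mg/dL" reading); low HDL-C means < 1.0 (men) / < 1.3 (women) mmol/L.
Baseline tables show mean ± SD and n (%) to one decimal.

## Multiplicity, clustering, triage

The effective number of tests is the smallest number of principal components
of the exposure correlation matrix reaching 90% cumulative variance; the
corrected threshold is 0.05/m (displayed to 4 decimals, e.g. 0.05/8 =
0.0063). k-means (k = 3 by default, best of 10 seeded restarts) on the rows
of the correlation matrix groups exposures, reporting each cluster's minimum
pairwise correlation.

An exposure is a **causal candidate** only if all of: primary IVW p below
the corrected threshold; strictly more than half of the available robust
estimators significant at 0.05; every available estimate sharing the IVW
sign; Egger intercept p > 0.05; MVMR support (MVMR-IVW p < 0.05 with sign
agreement, MVMR-median and MVMR-Lasso p < 0.05, MVMR-Egger intercept
p > 0.05); reverse-MR p ≥ 0.05; and Steiger filtering applied. The
intercept condition deserves emphasis: a *non-significant* intercept passes
— the opposite reading sometimes seen (requiring intercept p < 0.05) would
contradict both the parallel multivariable condition and the meaning of the
test, since a significant intercept is evidence of directional pleiotropy.

## Synthetic data

**GWAS generator.** Effect-allele frequencies ~ U(0.05, 0.95); true
per-variant effects scaled so Σ 2p(1−p)b² equals the target variance
explained; SEs use the standardized-trait approximation 1/√(2p(1−p)n)
(appropriate for rank-inverse-normalized traits; binary outcomes are
generated on the log-odds scale directly, without a liability model).
Exposure and outcome estimates are independent normal draws — two-sample
independence — and a chosen fraction of variants receives a direct outcome
effect α_j ~ N(pleio_mean, pleio_sd²). Effect alleles are oriented
exposure-increasing so a nonzero α mean is genuinely directional; three
effect-size shapes are available (half-normal default; bounded uniform for
validity-regime studies, since half-normal mass near zero produces
orientation flips and heavy-tailed ratios; signed normal for
orthogonality studies). LD, when requested, is compound-symmetric within
blocks and zero between — the simplest structure that exercises clumping;
estimate draws remain independent (realistic genome-wide LD is out of
scope).

**Cohort generator.** Metabolites are latent-factor blocks
(met = √ρ·F + √(1−ρ)·ε) giving within-block correlation ρ (default three
blocks at 0.85, mimicking tightly clustered lipoprotein panels); covariates
match a middle-aged population cohort (age ~ N(57, 8), 46% male, waist
~ N(90, 13), etc.) with literature-scale log hazard ratios; event times are
Weibull proportional hazards (shape 1.5, scale 170), centred linear
predictor, administrative censoring at 12.6 years — about 2% cumulative
incidence, matching a first-occurrence liver phenotype. Small fractions of
pre-enrollment diagnoses (0.5%) and non-NAFLD liver codes (0.5%) exercise
the phenotype filter.

**Benchmark study** (`simulate_study`): 20 exposures — five causal
(θ ∈ {0.3, −0.3, 0.5, −0.5, 0.4}), five nulls contaminated with directional
pleiotropy (40% invalid variants, α ~ N(0.08, 0.04²)), ten clean nulls —
each with 40 instruments at 3% variance explained, a shared waist covariate
(true effect 0.3 on disease) providing both univariable heterogeneity and
the MVMR second exposure, and a liver-fat trait (30 instruments, 5%
variance, n = 32,860) for reverse MR. Sample sizes mirror the data sources
the pipeline is designed for: ~115k for metabolite GWAS and a disease GWAS
of ~8.4k cases/770k controls; resulting instrument strength (overall
F ≈ 80+) matches the strong-instrument regime reported for such panels.

## Numerical and design notes

- Calibration of the IVW and Egger-intercept tests: under the exact normal
  model the φ ≥ 1 floor makes both slightly conservative (theoretical
  type-I error ≈ 0.039–0.044 for 10–80 instruments); calibration checks use
  50 instruments, where the rates are ≈ 0.044 and ≈ 0.049.
- Coverage at θ ≠ 0: the first-order ratio SE omits a θ²se²_X term whose
  relative size grows with n_outcome/n_exposure. With a 7× larger outcome
  GWAS, IVW coverage at θ = 0.3 is ≈ 92.5% even though the dispersion
  correction absorbs most of the omission; with matched sample sizes it is
  ≈ 95%. Recovery benchmarks therefore use matched sizes; the large-outcome
  regime is still exercised (null calibration is exact there, since the
  omitted term vanishes at θ = 0).
- Quantile-type robust estimators under one-sided contamination carry a
  finite-sample bias of order z_{0.5/(1−π)}·(ratio SE) — both this bias and
  the estimator's sampling SD scale with the ratio SE, so "recovery" is
  asserted relative to the estimator's own sampling SD (the same convention
  as the Cox per-SD check), not the Monte-Carlo SE of a replicate mean,
  which no quantile estimator could meet.
- Egger intercept recovery is demonstrated at very strong instruments
  (n = 10⁶, bounded-uniform effects): at metabolite-GWAS scale the
  intercept inherits a small regression-dilution bias; the I²_GX attenuation
  correction is deliberately out of scope.
- MVMR-Lasso λ selection walks the grid from large to small and stops at
  the first homogeneous valid subset — the stopping rule of the method as
  published; if no λ passes, the feasible subset with the smallest
  Q/(k_valid−p) is used.
- Degenerate inputs raise typed exceptions (`metabomr.exceptions`): zero
  exposure betas, insufficient instruments (k < 2 IVW, < 3 Egger/median,
  < 4 PRESSO, ≤ p MVMR), rank-deficient designs, profile maxima on grid
  boundaries, empty harmonizations.

## What the synthetic benchmarks do not show

The generators omit sample overlap between exposure and outcome GWAS,
population stratification, realistic genome-wide LD, liability-scale binary
traits, assortative mating, and time-varying hazards. Passing the suite
demonstrates the estimators' contracts and their behaviour under the stated
generative models — not that real-data results produced with this pipeline
are unbiased under violations of those models.
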