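# Methods

This note documents the statistical model behind `cordnorm`, the
calibration of the synthetic cohort generator, the numerical choices, and
what the package's validation does and does not demonstrate.

## 1. The analysis pipeline

The pipeline operates on a per-subject cohort table (demographics; TCA and
GM areas at C2-C3, C3-C4, T8-T9, T9-T10; brain volumes; skull/vertebra
metrics). Derived quantities are bookkeeping identities: WM = TCA − GM,
GM fraction = 100·GM/TCA, mean vertebra height = (anterior + posterior)/2,
sagittal vertebra area = mean height × AP diameter, and the bi-trapezoidal
area 2·[(mean height + middle height)/2 × AP diameter/2].

Four analysis stages:

1. **Descriptives** — Shapiro–Wilk normality, per-level moments and %RSD
   (= 100·SD/mean, n−1 denominator throughout), and Pearson correlation
   tables with pairwise deletion and per-cell n. No multiple-comparison
   correction is applied to these exploratory tables; the adjusted-means
   screen exposes an optional Bonferroni flag because the appropriate
   correction for that analysis is a user decision.
2. **Adjusted means** — least-square means: fit
   `outcome ~ group + covariates` by OLS and evaluate the prediction per
   group at the grand covariate mean. Equal-slopes model (no
   group×covariate interaction); sex comparisons adjust for age,
   median-split age comparisons adjust for sex (ties at the median go to
   the upper group); inference is a two-sided t test on the factor
   coefficient with residual df, and the 95% CI uses the same t
   distribution, so p < 0.05 ⟺ CI excludes 0.
3. **Normalization** — screen skull/vertebra metrics by Pearson r > 0.45
   (strict) against TCA or GM at the reference level (brain tissue volumes
   are excluded by design: they can be altered by the diseases the
   normalization is meant to serve); fit OLS models; retain when adjusted
   R² > 0.35; normalize via the residual formula with the fitting sample's
   covariate means frozen into the model; report
   %RSD reduction = 100·(1 − %RSD_norm/%RSD_meas).
4. **Transfer** — refit the reference-level covariate set at the other
   disc levels (coefficients are level-specific). Dropping a covariate on
   transfer is data-driven but deliberately narrow: only age is a drop
   candidate, and only for GM outcomes, where it is removed when its
   coefficient's two-sided p ≥ 0.05. This reproduces the published
   TCA-model → age-free GM-model collapse without hard-coding it, while
   TCA transfers always keep the full set.

Sex is stored as a category and coded numerically (F = 0, M = 1) in
exactly one place, the analysis frame's `sex_male` column.

## 2. Generative model of the synthetic cohort

The generator is first-class, tested code; its defaults are the study
conditions of the reference cohort (n = 32; 14 M / 18 F; ages 28–78).

Per subject, in order:

* **Sex** ~ Bernoulli(18/32 female).
* **Base covariates** (age, TICV, AP vertebra diameter, sagittal vertebra
  area) ~ multivariate normal conditional on sex, sharing one correlation
  matrix; per-sex age parents are N(46.8, 13.4²) for men and
  N(50.4, 15.1²) for women, truncated to [28, 78] years by resampling the
  whole covariate vector (resampling, not clipping, keeps the joint
  smooth). Within-sex SDs (TICV 125 000 mm³, AP diameter 1.2 mm, vertebra
  area 22 mm²) and male−female mean offsets (160 000 mm³, 1.0 mm, 25 mm²)
  are fixed anatomical choices typical of adult cohorts; the publication
  does not report them.
* **Remaining covariates** (brain tissue volumes, skull metrics) follow a
  one-factor model loading on TICV with fixed means/SDs/loadings — enough
  structure to make the descriptive tables meaningful, not calibrated
  quantities. Vertebra raw heights are reconstructed from the derived
  metrics (mean height = area/diameter; anterior/posterior split ~
  N(0, 0.8 mm); middle height = 0.94·mean + N(0, 0.35 mm)) so that the
  derived-metric identities hold exactly in the generated tables.
  Height/weight are drawn per sex with no pathway into the areas.
* **Cord areas**: each of the eight (level, measure) outcomes is
  `intercept(sex) + β'·covariates + ε`, with the residual 8-vector drawn
  once per subject from a correlated Gaussian (Cholesky factor of the
  residual correlation matrix). Draws violating 0 < GM < TCA are resampled
  (error if >10% of subjects need it; with the default calibration the
  constraint is ~10 SDs away).
* **Missingness**: two subjects lack the thoracic levels and two *other*
  subjects lack all brain/skeletal covariates, reproducing the reference
  cohort's pattern (the two groups are modelled as disjoint, so thoracic
  covariate models run at n = 28 complete cases and cervical ones at
  n = 30). Missingness is an absent record, never a zero.

A single integer seed drives everything; per-subject streams are split via
`SeedSequence(seed, spawn_key=(subject_index,))`, so extending a cohort
leaves earlier subjects' measurements unchanged (the missingness
*assignment*, a draw over subject indices, necessarily depends on n).

## 3. Calibration: from published summary statistics to generator defaults

The calibration is a packaged computation, not hand-tuned constants
(`cordnorm.calibration`). It rests on two pieces:

**Exact population moments.** For the model above, every statistic the
pipeline estimates has a closed form. Truncating age is handled exactly
through the conditional decomposition U = c + b·age + e of the
multivariate normal (only the age marginal changes; regression slopes on
age are invariant, variances and correlations shrink). Sex mixing uses the
standard two-component mixture moment formulas. Population OLS
coefficients, R² for any covariate subset, marginal slopes, least-square-
means sex differences and between-outcome correlations all derive from the
resulting mixture mean/covariance.

**Expected in-sample R².** In-sample residual normalization satisfies
%RSD_norm = %RSD_meas·√(1−R̂²) exactly, and the in-sample R̂² of an OLS fit
at sample size n with p covariates is biased upward:
E[1−R̂²] = (1−R²)·(n−p−1)/(n−1) to first order — the bias adjusted R²
removes. Residual SDs are therefore solved so that the *expected
in-sample* %RSD reduction at the study's complete-case n equals the
published reduction; equivalently, each published model's population R² is
set (approximately) to its published *adjusted* R². Converting the
published adjusted R² to the sample R² and using *that* as the population
value would systematically inflate replicate reductions by ~3–4
percentage points.

A weighted least-squares solver then reconciles the published targets,
which over-determine the model: level means/SDs, the age-adjusted sex
differences (4.60 mm² TCA and 1.51 mm² GM at C2-C3; 3.05 and 1.26 mm² at
T9-T10), the marginal age slopes (−2.0 mm²/decade TCA at C2-C3, −1.3 at
T9-T10), the TCA–TICV correlation (0.63), the population R² of the three
overlapping reference-level TCA models and the GM models, and the full
cross-level correlation table (e.g. 0.89 for adjacent TCA). Free
parameters are the per-outcome coefficients, direct sex offsets, residual
SDs, and three covariate-correlation parameters; coefficients are
initialized at, and weakly penalized toward, the published regression
coefficients. Identifying assumptions for the covariate correlations: the
TICV–AP-diameter correlation equals the product of the TICV–vertebra-area
and diameter–area correlations, and age correlates with the vertebra
metrics only through TICV. Cross-outcome residual correlations are then
solved cell-wise from the published correlation table and projected to the
nearest positive semi-definite matrix (eigenvalue clipping; the default
solution is comfortably PSD, minimum eigenvalue ≈ 0.06, and no cell needed
clipping).

Key solved values (defaults): age–TICV correlation −0.47,
AP-diameter–vertebra-area correlation 0.42; C2-C3 TCA model
β_age = −0.066 mm²/yr, β_TICV = 1.97·10⁻⁵ mm²/mm³, β_area = 0.093,
residual SD 5.12 mm²; adjacent-level TCA residual correlation 0.79.
Reconciling the published marginal age slope with the much smaller
conditional age coefficients *requires* the strong negative age–TICV
correlation: most of the cohort's age–area association is carried by the
head-size pathway. That is a property of this calibration, not an
anatomical claim.

Where published values conflict, the calibration follows the headline
numbers: the GM reduction target is 25% (the published models table's %RSD
ratio implies ~30%; its adjusted R² of 0.50 implies ~32% — mutually
inconsistent to begin with), and the TCA age slope follows the stated
−2 mm²/decade (the published median-split group difference of 7.12 mm²
would imply ~3 mm²/decade under a normal age distribution; consequently
the generator's median-split age tables show differences around 4.6 mm²,
not 7.1). Sex differences and slopes for C3-C4 and T8-T9 are not
published and are imputed proportionally to the level means.

## 4. What the generator does and does not emulate

It reproduces: the group-level first and second moments, the sex and age
effect structure, covariate–area and cross-level correlation structure,
the published models' explanatory power (and hence the %RSD-reduction
behaviour including its small-sample inflation), the missingness pattern,
and a T8-T9 GM model that typically fails the adjusted-R² gate.

It does not emulate: non-Gaussian features of real measurements
(segmentation errors, rater drift, digitization), any nonlinearity in the
age dependence, sex-specific covariances, disease effects, or distinct
per-metric measurement noise in the one-factor extras. The realized
within-cohort age SD is ≈11.6 years rather than the published 14.3: an SD
of 15.1 on a 50-year support is unattainable for any unimodal truncated
normal (the uniform caps at 14.4), so the generator keeps the published
per-sex parents and accepts the truncation-narrowed SD; all calibration
algebra uses the realized (truncated) moments, so downstream targets are
unaffected. Passing tests therefore show that the *pipeline* recovers the
statistics it was pointed at under a faithful Gaussian emulation — not
that it is robust to real-world measurement pathology.

## 5. Numerical choices

* Correlation matrices must be symmetric with unit diagonal; eigenvalues
  below −10⁻⁸ are an error, tiny negatives are repaired by eigenvalue
  clipping and diagonal renormalization.
* The screen threshold (0.45) and the adjusted-R² gate (0.35) are strict
  inequalities; a correlation exactly at the threshold is excluded.
* Median-split ties go to the upper ("≥ cutoff") group.
* OLS fits delegate to statsmodels; rank-deficient designs and
  complete-case counts below p + 3 raise errors rather than warnings.
* Degenerate generator configs (zero residual SDs, zero effects) are
  legal and produce deterministic intercept-valued cohorts; the Cholesky
  path tolerates PSD-singular matrices.
* Age plausibility bounds for cohort validation default to [18, 100]
  years and are configurable.

## 6. Problem sizes used in validation

Replicate analyses use 500 cohorts of n = 32 (fits at n = 28–30 complete
cases, as in the reference cohort); large-sample calibration checks use a
single cohort of n = 20 000. These sizes put Monte-Carlo error comfortably
below the comparison tolerances (e.g. SE of the mean reduction over 500
replicates ≈ 0.25 percentage points) while the full suite runs in about a
minute on one CPU.

## 7. Known limitations

* The calibration reproduces *population-level* structure; individual
  coefficients drift from the published point estimates (they were
  reconciled, not copied — see §3).
* The one-factor extras make the brain-volume correlation table
  qualitatively, not quantitatively, faithful.
* The `precentral_gm` covariate column is accepted in cohort tables but
  used nowhere, matching its status in the reference analysis.
* Whether the published model fits used 30 or 32 complete cases is not
  stated; this package reports the n actually used for every fit and
  adopts n = 30 (cervical) / 28 (thoracic) in the calibration
  arithmetic. Relatedly, the published measured %RSD for C2-C3 TCA
  (8.04%) differs from the ratio of the published group moments
  (7.0/79.7 = 8.78%); reductions are ratios and are insensitive to this,
  and the pipeline always reports both measured and normalized %RSD.
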