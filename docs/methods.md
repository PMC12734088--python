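# Methods

This note records the statistical model the package implements, the
conventions and defaults it commits to, what the synthetic-cohort
generator does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer from the code.

## Data model

Two tables define a cohort. The nerve table holds one row per decompressed
nerve root: patient id, root label, and the pre- and post-decompression MMG
stimulation thresholds in mA. The patient table holds anatomical region
(lumbar/cervical) and Numeric Pain Scale scores (integers 0–10) at baseline
and six weeks. Linkage is strict — a nerve row without a patient, or a
patient without nerves, is an error, because every derived metric is
patient-anchored. Thresholds are stored as decimals even though the
stimulation protocol (1 mA start, 1 mA increments) produces integers:
external datasets report averaged or fractional thresholds, so
non-integrality is a validation warning, not a constraint. A threshold
below the 1 mA stimulation floor is rejected outright.

Validation is advisory: it flags threshold worsening (post > pre, which the
measurement protocol should not produce), non-integer thresholds,
zero-baseline pain (excluded from improvement analyses downstream), and
thresholds above 30 mA, but never rejects a parsed cohort. Patients with
missing pain scores are dropped at read time with a logged exclusion; no
imputation is attempted.

## Metrics

All metrics are anchored to a physiologic reference threshold R, default
2.0 mA. Per nerve, baseline elevation is pre − R and post elevation is
max(post − R, 0); the Threshold Reduction Ratio is their relative
difference,

    TRR = [(pre − R) − max(post − R, 0)] / (pre − R).

A nerve contributes to TRR only when pre is *strictly* above R: at
pre = R the ratio is 0/0, and "nerves with baseline elevation" reads most
naturally as a strict inequality. TRR ≤ 1 always (overshoot below R clamps
the numerator), and a worsening nerve is allowed to drive it negative —
clamping would discard information, and the no-worsening expectation is
enforced only as a validation warning. Patient-level TRR is the unweighted
mean over elevated nerves and is undefined when there are none.

Threshold Excess is the residual patient-level elevation,
TE = max(agg(post) − R, 0) in mA, and percentage change is
(agg(pre) − agg(post)) / agg(pre). Three aggregations are supported: the
mean of the patient's thresholds (default), the index nerve (highest pre),
and the worst nerve (highest post); ties break to the first nerve in input
order, which is preserved from the file. For single-nerve patients all
three coincide. Under index/worst aggregation the patient's TRR is the
selected nerve's own ratio, mirroring single-nerve sensitivity analyses.

Because no canonical patient-level "percentage change" formula exists, two
views are computed and labeled: the ratio of aggregated thresholds above
(used in all comparisons) and, in the nerve-level summary, the mean of
per-nerve fractional reductions. The two differ materially on right-skewed
baselines (mean-of-ratios weights small baselines more), which is why both
are reported rather than silently picking one.

Pain outcomes: improvement fraction (pre − post)/pre, undefined at zero
baseline; MCID as (drop ≥ 2 points) OR (improvement ≥ 30%); complete
relief as a six-week score of exactly 0. Complete relief implies MCID
whenever the baseline is ≥ 1. Zero-baseline patients are excluded from all
improvement-fraction analyses but retained in counts.

## Inference

Every interval is 95%, computed with z = 1.959964 for internal
consistency; rounding happens only in the report formatter.

- **Correlations.** Pearson r; CI by Fisher z: tanh(atanh r ± z/√(n−3));
  two-sided p from t = r√(n−2)/√(1−r²) on n−2 df. Perfectly collinear
  data (|r| = 1) are nudged inside the open interval before atanh.
- **Dependent correlations.** Steiger's (1980) Z for two correlations
  sharing a variable, with the averaged-correlation covariance term: with
  r̄ = (r1y + r2y)/2 and
  c = [r12(1 − 2r̄²) − r̄²(1 − 2r̄² − r12²)/2] / (1 − r̄²)²,
  Z = (atanh r1y − atanh r2y)·√(n−3)/√(2 − 2c). This is the default
  variant in standard dependent-correlation tools; |c| ≥ 1 is reported as
  numeric degeneracy. The two correlations being compared are always
  computed on the identical patient subset (defined TRR *and* baseline
  pain) for parity.
- **OLS.** statsmodels, intercept added by the wrapper; t-based CIs with
  n − p df, R², Gaussian AIC. Rank-deficient designs raise an error naming
  the collinear columns. The adjusted model regresses the improvement
  fraction on TRR, baseline NPS, nerve count, and a cervical indicator.
- **Logistic regression.** Newton/IRLS maximum likelihood (statsmodels;
  tolerance 1e−8, 100 iterations). OR per unit = exp(b₁); Wald CI
  exp(b₁ ± z·SE); percentile bootstrap CI over patient-level resamples
  (default 2000, seeded, default seed 17); resamples that collapse to one
  class or separate are dropped and the effective count recorded.
  Separation and single-class outcomes raise typed errors. A
  zero-variance predictor short-circuits to slope 0 / OR 1 with an
  unbounded interval rather than failing on a singular design.
- **2×2 tables.** OR = ad/bc with the two-sided Fisher exact p
  (probability-mass summation, via scipy). A zero cell switches the OR to
  the Haldane–Anscombe +0.5 correction and flags the result. The exact
  test was chosen because the probability-summation convention is the most
  common two-sided definition; the report labels the method next to every
  p-value so a chi-square-based reading cannot be conflated with it.
- **Proportions.** Wilson score interval
  (p̂ + z²/2n ± z√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n), exact 0 and 1 at the
  k = 0 and k = n boundaries. The test suite verifies the closed form
  against bisection inversion of the score equation.

## Cross-validation

Leave-one-out CV of the simple linear model metric → improvement: for each
patient, fit on the other n − 1, predict the held-out outcome. Reported
statistics: cv_r, the Pearson correlation between held-out predictions and
actual outcomes; cv_R² defined as (cv_r)² — not 1 − SSE/SST — so that the
correlation and variance-explained columns are mutually consistent;
shrinkage = 100·(|apparent r| − cv_r)/|apparent r| (the magnitude is used
so that negatively-correlated predictors such as TE are treated
symmetrically); RMSE of held-out errors in improvement-fraction units; and
the mean held-out slope. For an inverse predictor the headline quantities
are RMSE, cv_R² and the slope rather than cv_r, which flips sign relative
to the apparent correlation by construction.

LOOCV is deterministic. K-fold uses a seeded partition stratified on the
outcome median (dealt round-robin within strata) to reduce fold-assignment
variance; the assignment is recorded in the output. Both run through one
shared code path — training-set sums are obtained by downdating the
full-data totals with the held-out fold — so k = n reproduces LOOCV
bit-exactly. A training fold with a constant predictor raises an error
naming the fold.

## Stratification and cut-points

Default strata follow the clinical presentation: TRR = 1.0 / 0.6 ≤ TRR <
1.0 / TRR < 0.6, and TE ∈ [0, 0.5) / [0.5, 2.5) / ≥ 2.5 mA. Categories
must be ordered, disjoint and exhaustive; a patient falling in no category
is an error, not a silent drop. Per stratum: n, mean improvement with a
Student-t interval (n − 1 df; truncation of the displayed interval to
[0, 100]% happens only in formatting), and the complete-relief rate with a
Wilson interval.

The sufficiency-plateau check correlates the mean post threshold with
improvement within the TE = 0 subset (patients at or below R), requiring
at least 4 such patients.

The cut-point scan classifies test-positive as agg(post) ≤ cutoff.
Candidates default to midpoints between sorted unique observed thresholds
plus R itself, which exhausts the distinct confusion matrices. The binary
outcome is a required parameter (complete relief, MCID, or any
improvement) and the report emits all three scans, because no single
outcome definition is canonical for this screen. AUC comes from the
Mann–Whitney rank statistic with tie correction and equals the trapezoidal
integral of the exhaustive ROC curve.

## Synthetic cohorts

The generator emulates the study-scale conditions: 42 patients, 1–6 nerves
each (categorical distribution with mean 2.70), 76% lumbar. Pre-decompression
thresholds are 1 mA + a rounded Gamma draw (shape 1.758, scale 3.658,
truncated at 25 mA), solved from a target elevation mean of 6.43 and SD
4.85 so the marginal threshold is ≈ 7.4 ± 4.9 mA with ≈ 90% above 2 mA.
Within-patient thresholds share an exchangeable Gaussian-copula correlation
of 0.3 — a plausibility choice, not anchored to published data, and
exposed as a config field. Recovery: an elevated nerve improves with
probability 0.89; improvers normalize (integer post ≤ R) with mixture
weight 0.52 or shed a Beta(2, 2)-distributed fraction of their elevation,
rounded to the integer grid within [3, pre − 1] mA. A pre = 3 mA improver
has no integer partial landing spot, so improvement forces normalization
there, raising the realized normalization fraction to ≈ 0.55. Beta(2, 2)
was chosen to match a pooled mean nerve-level reduction of ≈ 4.3 mA.
Worsening is never generated.

Baseline pain is 0 with probability 0.05 (generated specifically to
exercise the zero-baseline exclusion pathway), otherwise a rounded
Normal(7.3, 2.2) clipped to 1–10; the marginal is ≈ 6.8 ± 2.4. The outcome
coupling is

    improvement = clip(α + β·TE + ε, 0, 1),  ε ~ N(0, σ),

with defaults α = 0.92, β = −0.063, σ = 0.22, and the six-week score is
round(NPS_pre · (1 − improvement)) clipped to 0–10. Pain scores stay
integers end-to-end, so improvement fractions are rational — matching the
real instrument.

Two realism features attenuate recovered slopes and are deliberate: the
clip of the improvement fraction (at TE = 0 the mean sits near the ceiling,
where the truncated-normal derivative is ≈ 0.64) and the integer rounding
of the six-week score. At the default parameters the mean OLS estimate
across replicate cohorts lands near −0.055 for a generative β of −0.063;
parameter-recovery tolerances are ±0.01 rather than exact for this reason.

What the generator does **not** emulate: age/chronicity/comorbidity
effects on achievable thresholds, longitudinal trajectories beyond two
timepoints, region-specific threshold distributions, or any dependence of
pain on anything but TE. Passing recovery tests therefore demonstrates
correctness of the estimators under this generative model, not clinical
validity of the metrics on real cohorts.

## Problem sizes and seeds

The replicate experiments in the tests and the acceptance script use 200
cohorts of 42 patients for slope recovery and type-I-rate checks, and a
single 2000-patient cohort for the large-sample shrinkage limit — sizes at
which Monte-Carlo error is comfortably below the assertion tolerances.
Seeds: the generator takes one integer seed; replicate experiments derive
child seeds (< 2³¹) from it; bootstrap and k-fold default to seed 17 and
echo it in every output.

## Known limitations

- The package evaluates a single global reference threshold; patient-
  specific references (age- or comorbidity-adjusted) are out of scope.
- No multiple-comparison correction is applied anywhere, by design — the
  analysis battery is explicitly exploratory.
- No mixed-effects modeling of nerve-within-patient correlation: nerves
  are aggregated to the patient before inference.
- The clinical dataset the analysis was designed around is not
  redistributable; the one test that reproduces its headline statistics
  runs only where a local copy is provided, and all other guarantees rest
  on closed-form checks and the synthetic generator.
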