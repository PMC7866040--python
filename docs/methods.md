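# Methods

This note documents the models, defaults and design choices behind
`breathlasso`, and what the synthetic experiments do and do not show.

## Synthetic cohorts

**Distribution family.** Per compound and group, alveolar concentrations
are log-normal: positive support matches ppb concentrations, and the
published group summaries almost always show arithmetic mean above the
median (right skew).  A (median, mean) pair maps closed-form to
`log_mu = ln(median)`, `log_sigma = sqrt(2 ln(mean/median))`, so the
generated distribution reproduces both summaries exactly in expectation
(verified to 2% against 10^6-draw Monte Carlo in the tests).  Published
ranges are not fitted; some printed maxima imply heavier tails than a
log-normal, which the generator does not attempt to match.

A few published pairs have mean marginally *below* the median (e.g.
dinitrogen oxide in controls, 6438.0 vs 6311.9), which no log-normal can
produce.  `fit_lognormal_from_summary` rejects such pairs; the
reference-spec builder instead uses `|ln(mean/median)|` as the skew
estimate, treating those near-symmetric summaries as symmetric.

**Reference scenario.** Four groups — 45 controls, 36 lung
adenocarcinoma, 25 lung squamous-cell carcinoma, 52 colon adenocarcinoma
(158 subjects) — over a 95-compound panel.  Each case group differs from
controls only in the compounds of its discriminant panel (11, 9 and 13
compounds respectively); all other compounds are null (identical
case/control distributions).  Ages are uniform over each group's
published range; sex is Bernoulli with the published male fraction
(coded 0 = female, 1 = male).  Compounds are independent by default; a
Gaussian-copula `compound_correlation` option exists but defaults off,
since no covariance information is published.

**Environmental air.** One paired room-air record per subject:
`env_factor · exp(log_mu + ε)` with independent noise ε ~ N(0, 0.3²).
Retained compounds use `env_factor = 0.35` (room air well below
alveolar); the 11 designated contaminated compounds use `env_factor = 3`,
strong enough that the paired t-test excludes exactly that subset at
n = 158.

**CO2.** Passing samples draw from a truncated normal (mean 4.5%, SD
0.7%, truncated at the 2% threshold); a configurable `qc_fail_fraction`
of samples instead draws uniformly on [0.8, 2.0)%.  The default is 0
because the reference group sizes are post-QC analysis counts.  One
record is emitted per subject (analysis tables are per-subject even
where duplicate exhalations are collected).

## QC rules

* CO2 < 2% (strictly) discards a sample; exactly 2.0% is retained.
  Missing CO2 discards with its own reason code.
* Compound exclusion uses a **paired** two-sided t-test on
  (environmental − alveolar) differences — paired because the room-air
  sample is collected at the same time and place as the breath sample —
  with a one-directional rule: excluded iff mean difference > 0 and
  p < α (default 0.05, no multiple-testing correction, α configurable).
  A compound more abundant in alveolar air is never excluded.  Fewer
  than 3 pairs leaves the test undefined; the compound is retained with
  a warning.

## Penalized solver

The objective is the **sum** negative log-likelihood plus
`λ Σ_j w_j |β_j|` (intercept unpenalized).  Scaling the penalty against
the sum rather than the mean log-likelihood matches the
penalized-likelihood convention in which a λ of order 1–10 is meaningful
at n ≈ 80; a mean-scaled λ of that size would annihilate every
coefficient.

Optimization is proximal Newton: an IRLS quadratic majorization
(working weights `p(1−p)` floored at 1e-5) solved by cyclic coordinate
descent with soft-thresholding.  Numerical choices:

* convergence when the largest coefficient change in a sweep, and
  between outer reweightings, falls below 1e-7; at most 10^4 sweeps,
  non-convergence returns a flagged fit;
* the soft-threshold dead zone is widened by a relative 1e-12 so scores
  at the `λ_max` boundary produce exact zeros;
* standardized-scale coefficients are capped at |β| ≤ 30 with a warning
  (complete separation is possible at these n);
* infinite penalty weights force exact zeros (hard exclusion);
* `λ_max = max_j |x_jᵀ(y − ȳ)|/w_j` over finite-weight variables, exact
  for centered columns.

Correctness is established in the tests by objective equivalence
(≤ 1e-6) with a generic convex optimizer on random instances, KKT
residuals ≤ 1e-6 on every fit, equality with unpenalized
maximum-likelihood at λ = 0, and the null-model limit at λ ≥ λ_max.

**Cross-validation.** Outcome-stratified, seeded k-fold (default k = 50,
capped at n; k = n is leave-one-out) over a 50-point log grid spanning
three decades below λ_max, fitted warm-started from large to small λ.
The selected λ minimizes the mean held-out binomial deviance; exact ties
resolve to the smallest λ (denser model).  A training fold with a single
class is reshuffled once, then rejected.

## Iterated pipeline

1. **Screening** — LASSO (unit weights) at the CV-selected λ over all
   retained compounds plus age and sex; variables with nonzero
   coefficients are kept, their values discarded.  Age and sex are
   eligible, and standardized, at every stage: uniform treatment keeps
   the penalty comparable across variables, and no variable is forced
   into the model.
2. **Weight generation** — LASSO on the screened set; adaptive weights
   `w_j = 1/|β_j|` on the standardized scale (the scale the penalty
   operates on), infinite for zero coefficients.
3. **Adaptive LASSO** — weighted fit on the screened set at its own
   CV-selected λ.  The final nonzero set is always contained in the
   screened set.

**Bootstrap intervals.** B (default 200) outcome-stratified resamples;
each refits stages 2–3 on the fixed screened set with weights recomputed
per resample, then records original-scale coefficients (absent variables
contribute 0).  Intervals are percentile 2.5%/97.5%.  The stage λs are
held at the full-data CV selections: re-running 50-fold CV inside every
resample is both unstable at fold sizes of 1–2 and two orders of
magnitude more expensive, and fixing λ is the common convention when
bootstrapping penalized fits.  B = 10 is supported for comparability
with minimal designs but is far too few draws for stable percentiles;
200 is the default for that reason.  An interval that fails to bracket
its point estimate is flagged as bootstrap-unstable.

## Evaluation

Evaluation is **in-sample** (apparent performance) by default, the
convention for small-cohort discriminant panels; an honest
generalization estimate would need nested resampling, which is out of
scope.  The classification rule is `p ≥ threshold → case`, so the lowest
threshold always reproduces 100% sensitivity.  Percentages in threshold
tables are `100·count/n` rounded to 2 decimals.  AUC is the Mann–Whitney
statistic with ties counted ½; its standard error and the paired
ROC-area equality test use DeLong placement values, with a χ²(1)
reference for the paired test and a normal approximation for AUC
confidence intervals (the choice of approximation is labelled in the
output).  Compound profiles are standardized to the control group:
`z = (mean_case − mean_control)/sd_control`, zero control SD flagged.

## Problem sizes in the test suite

The simulation studies in the acceptance tests use 20 seeds per
contrast with 10-fold CV over a 30-point grid, and the bootstrap
coverage study uses 50 repeats at B = 200 — sizes chosen to keep the
full suite a few minutes on one CPU while preserving the selection
behavior of the full 50-fold procedure (verified to match `cv.glmnet`
curves fold-for-fold during development).

## Known limitations

* With ~84 candidate compounds at n ≈ 81, the largest chance
  |correlation| between a null compound and the outcome is ≈ 0.35 in
  expectation, and minimum-CV-deviance selection genuinely detects such
  dataset-level chance correlates in roughly half of null datasets.
  In-sample AUC on null data is therefore frequently well above 0.5
  even though selection is sparse.  This is a property of the
  lambda-min rule, not of this implementation.
* Percentile bootstrap intervals after adaptive-LASSO selection inherit
  selection bias; coverage for weak effects is below nominal.
* The generator emulates marginal summaries only: no compound
  covariance, no within-subject replicate variance, no batch or room
  effects, no instrument physics.  Passing tests demonstrate the
  statistical machinery, not clinical performance on real cohorts.
* Mass-only species are treated as opaque labels; chemical identity and
  calibration chemistry are out of scope.
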