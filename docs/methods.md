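# Methods

## The procedure

`moltstage` estimates when three molt-cycle milestones occur in the final
nymphal instar of the desert locust, relative to the adult molt
(ecdysis): the hemolymph ecdysteroid (20E) peak, the body-weight peak
(N5WP), and the transition of the inter-wing distance from linear growth
to a plateau (N5IW). The procedure is:

1. collapse per-nymph daily records into cohort means with SEMs, on the
   axis appropriate to each channel;
2. fit one parametric curve per channel by weighted nonlinear least
   squares (`scipy.optimize.least_squares`, trust-region reflective,
   ftol = xtol = gtol = 1e-12), with parameter covariance from the
   Jacobian at the optimum;
3. read each milestone off the fitted location parameter (directly for
   the Lorentzian center and the sigmoid midpoint; through the lognormal
   mode exp(µ − σ²) with a delta-method standard error for the weight
   peak);
4. correlate milestones by subtracting fitted locations, uncertainties
   added in quadrature — justified because the three fits consume
   disjoint response variables;
5. independently, stage each nymph by explicit rules on its raw
   non-invasive measurements (inter-wing distance ≥ 1.8 mm; weight drop
   ≥ 0.1 g from the running maximum; weight maximum before that drop).

Reported times use the "days prior to ecdysis" convention: positive
before the molt, one decimal day at report time, full precision
internally.

## Time axes

Two axes coexist. Measurements are taken on `day_of_instar` (days since
the molt into the fifth instar); analysis aligns records on
`days_prior_to_ecdysis = ecdysis_day − day_of_instar`, which removes
between-nymph variation in instar duration for features anchored to
ecdysis. The hormone pulse and the inter-wing transition are modelled on
the ecdysis-anchored axis; the weight trajectory is modelled on the
days-since-instar-start axis because the lognormal density needs a
positive argument.

One orientation subtlety: the linked linear/constant model rises linearly
and then plateaus as its argument *increases*, while "days prior to
ecdysis" runs backwards in developmental time. The inter-wing fit is
therefore performed on signed days relative to ecdysis (x = −days_prior,
negative before the molt), and the milestone is −µ̂. The Lorentzian is
symmetric, so it is fitted on days-prior directly. A sign flip leaves
standard errors unchanged.

## The models

* Lorentzian pulse f = (A/π)·σ/((x−µ)² + σ²): area A (pg·d/µL), peak
  A/(πσ) at µ, HWHM σ. Free: A, µ, σ.
* Area-scaled lognormal f = A/(σ√(2π))·exp(−(ln x − µ)²/(2σ²))/x: mode
  exp(µ − σ²). Free: A, µ, σ. Because weight is recorded as an increase
  relative to the first sampled day, the pipeline fits
  g(x) = f(x) − f(x_ref) (same parameters); fitting f alone to increase
  data would be misspecified by f(x_ref), which is small but nonzero.
  The reference day itself (increase identically zero) is excluded.
* Linked linear/constant f = (b₀ + b₁x)(1 − L) + A·L with logistic blend
  L = 1/(1+e^−(x−µ)/σ_link). Free: A, b₀, b₁, µ; σ_link is *fixed* during
  fitting (default 0.25 d) — with daily sampling the link width and the
  breakpoint location are poorly jointly identified, so the width is a
  declared smoothing scale, chosen well inside one sampling interval, and
  exposed as configuration. A pure-logistic special case (b₀ = b₁ = 0) is
  obtained by pinning those parameters; the default keeps the linear
  branch because the pre-transition growth is manifestly non-constant.
* The logistic is evaluated through its numerically stable branch on both
  tails, so arguments of magnitude ≫ 30 neither overflow nor lose more
  than ~1e-13 accuracy.

### Initialization and tie-breaks

Data-driven defaults, overridable per fit: Lorentzian µ₀ = argmax(y)
(earliest maximum on ties), σ₀ = span/6, A₀ = peak·πσ₀; lognormal by
method of moments treating the curve as a density in x; linked model
µ₀ at the largest drop in local slope (earliest on ties), linear branch
by least squares over the points at or before µ₀, plateau A₀ = last y.

### Weighting and covariance

With supplied per-point errors the fit minimizes Σ((y−f)/σᵢ)² and the
covariance is (JᵀJ)⁻¹ taken at face value, making χ²_red = χ²/dof a
genuine goodness-of-fit statistic. Without errors, unit weights are used
and the covariance is rescaled by χ²_red (the classical a-posteriori
estimate). The pipeline default weights by the empirical per-day SEMs
when at least (n_free + 2) points carry a positive SEM, otherwise unit
weights (noiseless cohorts have SEM 0 everywhere). Simulation studies
instead weight by the *true* SEM, noise_sd/√n: SEMs estimated from 14
animals are themselves noisy, and weighting by them inflates the expected
per-point contribution to ν/(ν−2) ≈ 1.18 (a Student-t² moment), so only
true-SEM weighting makes χ²_red a calibrated statistic.

Non-convergence and degenerate geometry are reported, not raised: the
`converged` flag reflects the optimizer's own status, and an exactly
singular Jacobian (e.g. a constant series fitted by the linked model,
where A and b₀ coincide) falls back to a pseudo-inverse covariance with a
note in the fit message. Downstream milestone extraction refuses
unconverged fits and the pipeline marks that channel's milestone absent
rather than failing the run.

## The synthetic cohort generator

No raw per-nymph cohorts of this design are publicly deposited, so the
generator emulates the study conditions: 14 female nymphs, synchronized
at the molt into the fifth instar, measured daily from day 4 until the
adult molt. Defaults (all configurable):

| quantity | default | rationale |
|---|---|---|
| instar duration | 9.0 ± 1.0 d, rounded to integer days, ≥ start+2 | typical fifth-instar duration for gregarious females; daily observation makes ecdysis day integral; floor guarantees ≥ 3 points |
| ecdysteroid pulse | A = 565 pg·d/µL, µ = 2.9 d prior, σ = 0.6 d | peak titer ≈ 300 pg/µL, pulse over ~2 days, peaking 2.9 d before ecdysis |
| weight increase | lognormal A = 2.6 g·d, µ = ln 7.2 + σ², σ = 0.18 | ≈ 0.8 g gain peaking 1.8 d before the mean ecdysis day; σ small enough that the curve is negligible at day 4, so "increase since day 4" is well defined |
| baseline weight | 1.5 g | day-0 body weight of a gregarious female fifth-instar nymph |
| inter-wing curve | slope 0.25 mm/d, plateau 2.0 mm, midpoint 3.1 d prior, σ_link 0.25 d | the smooth curve crosses 1.8 mm at the midpoint, tying the fitted milestone to the staging threshold; midpoint 0.2 d before the hormone peak |
| noise sd | 0.04 g / 0.06 mm / 60 pg/µL | weighing noise must sit well below the 0.1 g staging threshold, or the published decrease rule would fire spuriously day-to-day; titer noise gives a peak-time se near 0.1 d at n = 14 |
| missingness | 0 (configurable record-wise rate) | no dropout scheme is modelled; attrition from the synchronized group to the followed group is likewise not modelled |

Noise is additive Gaussian, independent across records, truncated at zero
(measured quantities are non-negative). The hormone and inter-wing truth
curves are shared across nymphs on the ecdysis-anchored axis; the weight
truth is shared on the start axis, so a cohort's weight peak in
days-prior terms moves with its realized mean instar duration — visible
as between-cohort scatter of the N5WP estimate (sd ≈ 0.27 d at n = 14),
which replicate averaging removes.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about real data: heteroscedastic, likely multiplicative
titer noise (real EIA variability grows with the titer); between-nymph
amplitude and timing variation in the underlying curves (only ecdysis-day
jitter is modelled); serial correlation within a nymph; attrition;
non-daily or missed sampling beyond uniform record-wise missingness. With
additive constant-sd titer noise of 60 pg/µL, the low Lorentzian tail is
partly truncated at zero, a deliberate mild misspecification that real
positive-valued data share; it shifts the titer-channel mean χ²_red to
≈ 1.07 in the recovery study.

## Simulation studies and problem sizes

The recovery study (`analysis/05_recovery_study.py`, also exercised by
the test suite) runs 200 replicate cohorts at the default design with
true-SEM weighting: all fits converge, every milestone estimator's bias
is below 0.02 d, RMSE is below its mean reported se, and mean χ²_red is
1.07 (titer) and 0.98 (inter-wing). The weight channel's χ²_red (≈ 0.65)
is not a calibrated statistic: subtracting the shared first-day record
correlates the per-day residuals (pairwise correlation 1/2), which the
diagonal weighting ignores. Wald-interval checks use 1000 single-series
fits (68% coverage within [60%, 76%]) and 200 cohorts (95% interval
coverage ≥ 90% for the weight peak). Delta-method standard errors are
validated against 10⁵-draw Monte-Carlo propagation from the fit
covariance (agreement within 10%). `scripts/acceptance.py` averages 25
replicate cohorts, enough to pin the cross-cohort means to ≈ 0.05 d.

## Staging rules

The 0.1 g decrease is judged against the running maximum by default
(robust to one noisy plateau day); comparison to the previous day is
available as a configuration switch, and matters exactly when the decline
is gradual. Ties for the maximum weight break to the latest qualifying
day, since the weight peak immediately precedes the decrease. Days with a
missing measurement cannot fire a rule but do not abort staging; a rule
that never fires leaves its milestone absent, and cohort summaries report
the count of nymphs where each rule fired. Rule-based N5WP lands ~0.2 d
earlier than the fitted weight peak on average — daily discretization plus
argmax noise — which is why the fitted estimate is preferred for timing
claims and the rules for real-time, per-animal decisions.

## Known limitations

* Milestone uncertainties assume the three channels are independent;
  shared developmental noise in a real cohort would correlate them.
* The cohort-mean fit (the default) estimates the *population* curve's
  features; per-nymph fits then averaging is possible through the same
  fit engine but is not the packaged default.
* With daily sampling, σ_link is not estimable and its fixed value is a
  modelling assumption; the midpoint µ is insensitive to doubling it on
  sharp-breakpoint data (checked in the tests), but extreme values would
  bias the milestone.
* The generator's truths are exactly the fitted model families, so
  recovery studies demonstrate estimator correctness, not robustness to
  functional-form misspecification (beyond the zero-truncation noted
  above).
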