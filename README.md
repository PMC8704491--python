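# moltstage

Timing the molt cycle of fifth-instar locust nymphs from longitudinal
measurements.

In the final (N5) nymphal instar of the desert locust, a pulse of the
steroid hormone 20-hydroxyecdysone (20E) in the hemolymph commits the
animal to the adult molt, and two externally visible characteristics track
the same program: body weight rises and then falls shortly before ecdysis,
and the gap between the wing primordia (the *inter-wing distance*) grows
linearly and then plateaus. `moltstage` turns daily per-nymph records of
these three channels into estimated molt-cycle milestones with
uncertainties, and classifies individual nymphs into stages from the two
non-invasive measurements alone — useful for scheduling dissections or
treatments at defined physiological moments without bleeding the animal.

## Models and milestones

Each channel's cohort-mean trajectory is fitted by weighted nonlinear
least squares; the location parameter µ of each curve carries the timing
information:

* **Ecdysteroid titer** (pg/µL), on the days-prior-to-ecdysis axis:
  a Lorentzian pulse

  f(x; A, µ, σ) = (A/π) · σ / ((x − µ)² + σ²),

  peak at µ, half-width σ. The milestone is the fitted µ.

* **Body-weight increase** (g, relative to the first sampled day), on the
  days-since-instar-start axis: an area-scaled lognormal

  f(x; A, µ, σ) = A/(σ√(2π)) · exp(−(ln x − µ)²/(2σ²)) / x,

  whose mode exp(µ − σ²) is the weight peak (N5WP); its standard error
  follows from the delta method with gradient (m, −2σm), m = exp(µ − σ²),
  applied to the fit covariance. (The pipeline actually fits
  f(x) − f(x_ref), the correctly specified model for data recorded as an
  increase since the reference day.)

* **Inter-wing distance** (mm), on forward time relative to ecdysis: a
  linear branch blended into a plateau by a logistic link,

  f(x) = (b₀ + b₁x)(1 − L) + A·L,  L = 1/(1 + e^−(x−µ)/σ_link),

  with the link width σ_link fixed (default 0.25 d). The fitted sigmoid
  midpoint µ marks the N5IW milestone, empirically the moment the
  inter-wing distance reaches ≈ 1.8 mm.

Milestones are correlated by subtraction of the fitted µ values, with
uncertainties added in quadrature (independent measurement channels), and
every fit reports its reduced chi-square χ²_red = χ²/dof.

Rule-based staging works per nymph without any fitting: N5IW is the first
day the inter-wing distance reaches 1.8 mm, N5WD the first day body weight
has dropped ≥ 0.1 g from its running maximum, and N5WP the day of maximum
weight before that drop.

Because raw cohorts of this kind are rarely deposited, a seeded generator
(`moltstage.simulate`) produces synthetic cohorts with exactly this
parametric structure — by default 14 female nymphs measured daily from day
4 of the instar until the adult molt — so the whole pipeline is testable
and its estimators can be calibrated by simulation.

## Worked example

```sh
moltstage run --config run.yaml --out results/
```

with `run.yaml` containing `{cohort: {}, seed: 1}` (an empty cohort block
uses the default study-like configuration), prints:

```
milestones (from fitted trajectories):
  ecdysteroid peak: 2.9 ± 0.1 days prior to ecdysis
  weight peak (N5WP): 1.5 ± 0.0 days prior to ecdysis
  inter-wing midpoint (N5IW): 3.1 ± 0.1 days prior to ecdysis

offsets (subtraction of fitted locations):
  ecdysteroid_peak 1.4 ± 0.1 days prior to weight_peak
  ecdysteroid_peak 0.2 ± 0.1 days after iw_midpoint
  weight_peak 1.6 ± 0.1 days after iw_midpoint
```

Read: in this simulated cohort the hormone pulse peaks 2.9 days before the
adult molt; the inter-wing distance hits its transition 0.2 days earlier
still; the weight peak follows the hormone peak by about a day and a half.
(A single 14-nymph cohort carries real sampling scatter — the weight peak
here landed at 1.5 d prior because this cohort's realized mean instar
duration fell below its expectation; averaging replicate cohorts recovers
1.8 d, see below.) The run directory also contains the per-fit JSONs with
covariances and χ²_red, the staging TSV, and a provenance-stamped report
regenerable byte-identically from the same config and seed.

The numbered scripts under `analysis/` run the same steps as a narrative:
simulate, fit, extract milestones and offsets, stage, and finally a
200-replicate parameter-recovery study (`05_recovery_study.py`) that
measures each estimator's bias (< 0.02 d), RMSE versus its reported
standard error, and χ²_red calibration.

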