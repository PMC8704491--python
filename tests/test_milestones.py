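"""Milestone extraction, delta-method propagation, offset arithmetic."""

import dataclasses
import math

import numpy as np
import pytest

from moltstage.config import CohortConfig
from moltstage.errors import InferenceError, InputError
from moltstage.fitting import FitResult, fit_model
from moltstage.milestones import (
    MilestoneEstimate,
    ecdysteroid_peak_time,
    iw_midpoint_time,
    milestone_offset,
    weight_peak_time,
)
from moltstage.models import (
    linked_linear_constant_spec,
    lognorm_model,
    lognorm_spec,
    lorentzian_spec,
)
from moltstage.study import generative_truths


def _make_fit(spec, params, cov, converged=True):
    cov = np.asarray(cov, dtype=float)
    ses = dict(zip(spec.free_params, np.sqrt(np.diag(cov))))
    return FitResult(
        model=spec,
        params=dict(params),
        covariance=cov,
        standard_errors=ses,
        chi2_red=1.0,
        dof=5,
        residuals=np.zeros(8),
        converged=converged,
        n_points=8,
    )


class TestEcdysteroidPeak:
    def test_reads_mu_and_its_se(self):
        fit = _make_fit(
            lorentzian_spec(),
            {"A": 500.0, "mu": 2.9, "sigma": 0.6},
            np.diag([25.0, 0.01, 0.04]),
        )
        m = ecdysteroid_peak_time(fit)
        assert (m.time, m.se) == (2.9, pytest.approx(0.1))
        assert m.render() == "2.9 ± 0.1 days prior to ecdysis"

    def test_unconverged_fit_raises(self):
        fit = _make_fit(
            lorentzian_spec(),
            {"A": 1.0, "mu": 0.0, "sigma": 1.0},
            np.eye(3),
            converged=False,
        )
        with pytest.raises(InferenceError):
            ecdysteroid_peak_time(fit)

    def test_zero_noise_fit_recovers_generative_mu(self, zero_noise_config):
        from moltstage.pipeline import fit_channels, prepare_channels
        from moltstage.simulate import generate_cohort

        table = generate_cohort(zero_noise_config)
        fits = fit_channels(prepare_channels(table))
        m = ecdysteroid_peak_time(fits["ecdysteroid"])
        assert m.time == pytest.approx(
            zero_noise_config.ecdysteroid_peak.mu, abs=1e-6
        )

    def test_monte_carlo_unbiasedness_in_gaussian_regime(self):
        """Mean estimate over 500 cohorts within 2*(se/sqrt(500)) of truth.

        Uses a broad hormone pulse whose tails stay well above zero, so the
        additive Gaussian noise model is self-consistent (no truncation).
        """
        from moltstage.config import NoiseSD, PeakCurve
        from moltstage.study import milestone_recovery_study

        cfg = dataclasses.replace(
            CohortConfig(),
            ecdysteroid_peak=PeakCurve(A=300 * math.pi * 1.5, mu=2.9, sigma=1.5),
            noise_sd=NoiseSD(weight=0.08, iw=0.06, ecdysteroid=20.0),
        )
        study = milestone_recovery_study(cfg, 500, seed=55, weighting="true")
        bias = (study["ecdysteroid_est"] - 2.9).mean()
        tol = 2 * study["ecdysteroid_se"].mean() / math.sqrt(500)
        assert abs(bias) < tol


class TestWeightPeak:
    def test_sigma_to_zero_limit(self):
        mu, sigma = 2.0, 1e-6
        se_mu = 0.05
        fit = _make_fit(
            lognorm_spec(),
            {"A": 2.0, "mu": mu, "sigma": sigma},
            np.diag([0.01, se_mu**2, 1e-12]),
        )
        m = weight_peak_time(fit, ecdysis_day=9.0)
        mode = math.exp(mu - sigma**2)
        assert m.time == pytest.approx(9.0 - math.exp(mu), rel=1e-9)
        assert m.se == pytest.approx(mode * se_mu, rel=1e-6)

    def test_delta_method_agrees_with_monte_carlo_propagation(self):
        """10^5 draws from the fit covariance reproduce the delta-method se."""
        rng = np.random.default_rng(31)
        x = np.arange(4.0, 10.0 + 1e-9, 0.5)
        truth = {"A": 2.6, "mu": 2.0, "sigma": 0.18}
        y = lognorm_model(x, **truth) + rng.normal(0, 0.02, len(x))
        fit = fit_model(lognorm_spec(), x, y, y_err=np.full_like(x, 0.02))
        assert fit.converged
        m = weight_peak_time(fit, ecdysis_day=9.0)

        mean = np.array([fit.params["mu"], fit.params["sigma"]])
        cov = fit.cov_submatrix(("mu", "sigma"))
        draws = rng.multivariate_normal(mean, cov, size=100_000)
        modes = np.exp(draws[:, 0] - draws[:, 1] ** 2)
        assert m.se == pytest.approx(modes.std(), rel=0.10)

    def test_coverage_of_95_percent_wald_interval(self, recovery_study_200):
        """|estimate - truth| <= 1.96 se in at least 90% of 200 replicates."""
        config, study = recovery_study_200
        truth = generative_truths(config)["weight_mode"]
        err = np.abs(study["weight_mode_est"] - truth)
        covered = (err <= 1.96 * study["weight_se"]).mean()
        assert covered >= 0.90

    def test_unconverged_fit_raises(self):
        fit = _make_fit(
            lognorm_spec(), {"A": 1.0, "mu": 2.0, "sigma": 0.2},
            np.eye(3), converged=False,
        )
        with pytest.raises(InferenceError):
            weight_peak_time(fit, 9.0)


class TestIWMidpoint:
    def test_zero_noise_fit_recovers_generative_mu(self, zero_noise_config):
        from moltstage.pipeline import fit_channels, prepare_channels
        from moltstage.simulate import generate_cohort

        table = generate_cohort(zero_noise_config)
        fits = fit_channels(prepare_channels(table))
        m = iw_midpoint_time(fits["iw"], axis="days_rel_ecdysis")
        assert m.time == pytest.approx(zero_noise_config.iw_curve.mu, abs=1e-6)

    def test_axis_conventions(self):
        fit = _make_fit(
            linked_linear_constant_spec(0.25),
            {"A": 2.0, "b0": 2.375, "b1": 0.25, "mu": -3.1},
            np.diag([1e-4, 1e-4, 1e-4, 0.01]),
        )
        m = iw_midpoint_time(fit, axis="days_rel_ecdysis")
        assert m.time == pytest.approx(3.1)
        assert m.se == pytest.approx(0.1)
        direct = iw_midpoint_time(fit)  # days-prior fit: mu taken as-is
        assert direct.time == pytest.approx(-3.1)
        with pytest.raises(InputError):
            iw_midpoint_time(fit, axis="hours")

    def test_midpoint_insensitive_to_link_width_on_sharp_breakpoint(self):
        """Doubling sigma_link barely moves mu on noiseless breakpoint data."""
        x = np.arange(-6.0, 0.0 + 1e-9, 0.25)
        # noiseless sharp corner: linear up to the breakpoint, flat beyond
        y = np.where(x < -3.1, 2.375 + 0.25 * x, 2.375 + 0.25 * -3.1)
        mus = []
        for sl in (0.25, 0.5):
            fit = fit_model(linked_linear_constant_spec(sl), x, y)
            assert fit.converged
            mus.append(fit.params["mu"])
        assert mus[0] == pytest.approx(mus[1], abs=0.15)


class TestOffsets:
    def test_identical_milestones(self):
        a = MilestoneEstimate("weight_peak", 1.8, 0.4)
        o = milestone_offset(a, a)
        assert o.delta == 0.0
        assert o.se == pytest.approx(math.sqrt(2) * 0.4)

    def test_printed_milestones_offset_arithmetic(self):
        wp = MilestoneEstimate("weight_peak", 1.8, 0.4)
        peak = MilestoneEstimate("ecdysteroid_peak", 2.9, 0.1)
        o = milestone_offset(wp, peak)
        assert o.delta == pytest.approx(-1.1)
        assert o.se == pytest.approx(math.sqrt(0.4**2 + 0.1**2))
        assert round(o.se, 1) == 0.4
        assert "1.1" in o.render() and "after" in o.render()

    def test_se_symmetric_delta_antisymmetric(self):
        a = MilestoneEstimate("iw_midpoint", 3.1, 0.07)
        b = MilestoneEstimate("ecdysteroid_peak", 2.9, 0.09)
        ab, ba = milestone_offset(a, b), milestone_offset(b, a)
        assert ab.delta == -ba.delta
        assert ab.se == ba.se

    def test_translation_invariance(self):
        a = MilestoneEstimate("a", 3.1, 0.1)
        b = MilestoneEstimate("b", 2.9, 0.1)
        c = 4.2
        shifted = milestone_offset(
            MilestoneEstimate("a", 3.1 + c, 0.1), MilestoneEstimate("b", 2.9 + c, 0.1)
        )
        assert shifted.delta == pytest.approx(milestone_offset(a, b).delta)

    def test_mixed_axes_rejected(self):
        a = MilestoneEstimate("a", 1.0, 0.1)
        b = MilestoneEstimate("b", 1.0, 0.1, axis="day_of_instar")
        with pytest.raises(InputError):
            milestone_offset(a, b)
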