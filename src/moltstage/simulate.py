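"""Seeded synthetic fifth-instar cohorts.

The generator draws one integer ecdysis day per nymph, evaluates the three
generative curves on their native axes, adds independent Gaussian noise
truncated at zero, and returns a tidy per-nymph, per-day table.  Aligning
records on days prior to ecdysis removes the between-nymph jitter of the
instar duration for the two curves anchored to ecdysis (hormone pulse,
inter-wing transition); the weight trajectory is anchored to the start of
the instar instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .errors import InputError
from .models import linked_linear_constant_model, lognorm_model, lorentzian_model
from .rng import substream

MEASUREMENT_COLUMNS = ("weight", "inter_wing_distance", "ecdysteroid_titer")

COLUMNS = (
    "nymph_id",
    "sex",
    "day_of_instar",
    "ecdysis_day",
    "days_prior_to_ecdysis",
    "weight",
    "inter_wing_distance",
    "ecdysteroid_titer",
)


def ecdysteroid_truth(days_prior: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Noiseless hemolymph titer on the days-prior-to-ecdysis axis."""
    p = config.ecdysteroid_peak
    return lorentzian_model(days_prior, A=p.A, mu=p.mu, sigma=p.sigma)


def weight_truth(day_of_instar: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Noiseless absolute body weight on the days-since-instar-start axis."""
    w = config.weight_curve
    return config.weight_baseline + lognorm_model(
        day_of_instar, A=w.A, mu=w.mu, sigma=w.sigma
    )


def iw_truth(days_prior: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Noiseless inter-wing distance on the days-prior-to-ecdysis axis.

    The linked model lives on forward time relative to ecdysis
    (x = -days_prior): the linear rise precedes the plateau.
    """
    c = config.iw_curve
    x = -np.asarray(days_prior, dtype=float)
    return linked_linear_constant_model(
        x, A=c.plateau, b0=c.intercept, b1=c.slope, mu=-c.mu, sigma_link=c.sigma_link
    )


def _draw_ecdysis_days(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(config.instar_duration_mean, config.instar_duration_sd,
                     size=config.n_nymphs)
    days = np.rint(raw).astype(int)
    # daily observation: guarantee at least 3 sampling days per nymph
    return np.maximum(days, config.sampling_start_day + 2)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy table.

    One row per (nymph, day) from ``sampling_start_day`` through the
    nymph's ecdysis day.  Measurement noise is additive Gaussian with the
    configured sds, truncated at zero; with ``missing_rate`` > 0 a record's
    measurements are jointly blanked with that probability.  Deterministic
    for a fixed ``config.seed``.
    """
    config.validate()
    rng_days = substream(config.seed, "ecdysis-days")
    rng_noise = substream(config.seed, "measurement-noise")
    rng_miss = substream(config.seed, "missingness")

    ecdysis_days = _draw_ecdysis_days(config, rng_days)

    frames = []
    for i, ecd in enumerate(ecdysis_days):
        days = np.arange(config.sampling_start_day, ecd + 1)
        prior = ecd - days.astype(float)
        n = len(days)
        weight = weight_truth(days.astype(float), config)
        iw = iw_truth(prior, config)
        titer = ecdysteroid_truth(prior, config)
        weight = weight + rng_noise.normal(0.0, config.noise_sd.weight, n)
        iw = iw + rng_noise.normal(0.0, config.noise_sd.iw, n)
        titer = titer + rng_noise.normal(0.0, config.noise_sd.ecdysteroid, n)
        frames.append(
            pd.DataFrame(
                {
                    "nymph_id": f"N{i + 1:03d}",
                    "sex": config.sex,
                    "day_of_instar": days,
                    "ecdysis_day": int(ecd),
                    "days_prior_to_ecdysis": prior,
                    "weight": np.clip(weight, 0.0, None),
                    "inter_wing_distance": np.clip(iw, 0.0, None),
                    "ecdysteroid_titer": np.clip(titer, 0.0, None),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)[list(COLUMNS)]

    if config.missing_rate > 0:
        miss = rng_miss.random(len(table)) < config.missing_rate
        table.loc[miss, list(MEASUREMENT_COLUMNS)] = np.nan
    return table


def cohort_means(
    table: pd.DataFrame,
    axis: str = "days_prior_to_ecdysis",
    values: tuple[str, ...] = MEASUREMENT_COLUMNS,
) -> pd.DataFrame:
    """Per-time-point mean and SEM over nymphs with a present value.

    Returns a tidy frame with columns (variable, time, mean, sem, n); the
    SEM is left NaN where fewer than two nymphs contribute.
    """
    if axis not in {"day_of_instar", "days_prior_to_ecdysis"}:
        raise InputError(f"unknown axis {axis!r}")
    if table.empty:
        raise InputError("cohort table is empty")
    out = []
    for var in values:
        g = table.dropna(subset=[var]).groupby(axis)[var]
        agg = g.agg(mean="mean", sd="std", n="count").reset_index()
        agg["sem"] = np.where(agg["n"] >= 2, agg["sd"] / np.sqrt(agg["n"]), np.nan)
        agg["variable"] = var
        agg = agg.rename(columns={axis: "time"})
        out.append(agg[["variable", "time", "mean", "sem", "n"]])
    return pd.concat(out, ignore_index=True).sort_values(
        ["variable", "time"], ignore_index=True
    )


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"cohort file {path} lacks columns: {sorted(missing)}")
    return table
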