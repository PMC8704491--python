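"""Milestone extraction from fitted trajectories and offset arithmetic.

Each milestone is a time point on the days-prior-to-ecdysis axis
(positive before the adult molt) with a delta-method standard error
propagated from the fit covariance.  Offsets between milestones are
differences of the fitted locations; their uncertainties add in
quadrature because the three channels are fitted to disjoint response
variables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InferenceError, InputError
from .fitting import FitResult

DAYS_PRIOR = "days_prior_to_ecdysis"

__all__ = [
    "MilestoneEstimate",
    "OffsetEstimate",
    "InferenceError",
    "ecdysteroid_peak_time",
    "weight_peak_time",
    "iw_midpoint_time",
    "milestone_offset",
]


@dataclass(frozen=True)
class MilestoneEstimate:
    """A developmental time point, in days prior to ecdysis, with its se."""

    name: str
    time: float
    se: float
    axis: str = DAYS_PRIOR
    source_fit: FitResult | None = None

    def __post_init__(self):
        if not math.isfinite(self.time):
            raise InferenceError(f"{self.name}: non-finite time {self.time}")
        if self.se < 0:
            raise InferenceError(f"{self.name}: negative se {self.se}")

    def render(self) -> str:
        se = "n/a" if not math.isfinite(self.se) else f"{self.se:.1f}"
        return f"{self.time:.1f} ± {se} days prior to ecdysis"


@dataclass(frozen=True)
class OffsetEstimate:
    """delta = time(a) - time(b); positive means a earlier (more days prior)."""

    from_milestone: str
    to_milestone: str
    delta: float
    se: float

    def render(self) -> str:
        se = "n/a" if not math.isfinite(self.se) else f"{self.se:.1f}"
        if self.delta >= 0:
            rel = f"{self.delta:.1f} ± {se} days prior to"
        else:
            rel = f"{-self.delta:.1f} ± {se} days after"
        return f"{self.from_milestone} {rel} {self.to_milestone}"


def _require_converged(fit: FitResult, what: str) -> None:
    if not fit.converged:
        raise InferenceError(f"cannot extract {what} from an unconverged fit")


def ecdysteroid_peak_time(fit: FitResult) -> MilestoneEstimate:
    """Peak of the Lorentzian titer pulse: the fitted center mu.

    The fit is performed directly on the days-prior axis, so mu and its
    standard error carry over unchanged.
    """
    _require_converged(fit, "ecdysteroid peak")
    return MilestoneEstimate(
        name="ecdysteroid_peak",
        time=float(fit.params["mu"]),
        se=float(fit.standard_errors["mu"]),
        source_fit=fit,
    )


def weight_peak_time(fit: FitResult, ecdysis_day: float) -> MilestoneEstimate:
    """Mode of the lognormal weight trajectory, converted to days prior.

    The mode on the days-since-instar-start axis is m = exp(mu - sigma^2);
    its se follows from the delta method with gradient
    (dm/dmu, dm/dsigma) = (m, -2*sigma*m) applied to the (mu, sigma) block
    of the fit covariance.  The conversion days_prior = ecdysis_day - m is
    a shift and leaves the se unchanged.
    """
    _require_converged(fit, "weight peak")
    mu = float(fit.params["mu"])
    sigma = float(fit.params["sigma"])
    m = math.exp(mu - sigma * sigma)
    grad = np.array([m, -2.0 * sigma * m])
    cov = fit.cov_submatrix(("mu", "sigma"))
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    return MilestoneEstimate(
        name="weight_peak",
        time=float(ecdysis_day) - m,
        se=se,
        source_fit=fit,
    )


def iw_midpoint_time(fit: FitResult, axis: str = DAYS_PRIOR) -> MilestoneEstimate:
    """Midpoint of the inter-wing linear-to-plateau transition.

    ``axis`` names the axis the fit was performed on: ``days_prior_to_ecdysis``
    (mu already in days prior) or ``days_rel_ecdysis`` (forward time,
    x = -days_prior, so the milestone is -mu).  A sign flip leaves the
    standard error unchanged.
    """
    _require_converged(fit, "inter-wing midpoint")
    mu = float(fit.params["mu"])
    if axis == DAYS_PRIOR:
        time = mu
    elif axis == "days_rel_ecdysis":
        time = -mu
    else:
        raise InputError(f"unknown axis {axis!r}")
    return MilestoneEstimate(
        name="iw_midpoint",
        time=time,
        se=float(fit.standard_errors["mu"]),
        source_fit=fit,
    )


def milestone_offset(a: MilestoneEstimate, b: MilestoneEstimate) -> OffsetEstimate:
    """Difference of two milestone times with quadrature-propagated se.

    The two fits use disjoint response variables, so their uncertainties
    are treated as independent.  Rounding happens only at report time.
    """
    if a.axis != b.axis:
        raise InputError(f"milestones on different axes: {a.axis!r} vs {b.axis!r}")
    return OffsetEstimate(
        from_milestone=a.name,
        to_milestone=b.name,
        delta=a.time - b.time,
        se=math.sqrt(a.se**2 + b.se**2),
    )


def milestones_to_json(milestones, offsets, path: str | Path) -> None:
    doc = {
        "milestones": [
            {"name": m.name, "days_prior_to_ecdysis": m.time, "se": m.se}
            for m in milestones
        ],
        "offsets": [
            {
                "from": o.from_milestone,
                "to": o.to_milestone,
                "delta_days": o.delta,
                "se_days": o.se,
            }
            for o in offsets
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
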