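"""Weighted nonlinear least-squares fitting with honest diagnostics.

``fit_model`` minimizes sum(((y - f(x)) / y_err)**2) with
:func:`scipy.optimize.least_squares`, reports the parameter covariance
from the Jacobian at the optimum, and the reduced chi-square
chi2_red = chi2 / dof.  When no measurement errors are supplied the fit
uses unit weights and the covariance is rescaled by chi2_red (the
classical a-posteriori error estimate); when errors are supplied they are
taken at face value so chi2_red is a genuine goodness-of-fit statistic.
Non-convergence is reported through the ``converged`` flag, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError
from .models import ModelSpec

__all__ = ["FitResult", "fit_model", "InputError"]


@dataclass
class FitResult:
    model: ModelSpec
    params: dict[str, float]
    covariance: np.ndarray  # over free params, in spec order
    standard_errors: dict[str, float]
    chi2_red: float
    dof: int
    residuals: np.ndarray  # weighted, y-units/err-units
    converged: bool
    n_points: int
    message: str = ""

    @property
    def free_params(self) -> tuple[str, ...]:
        return self.model.free_params

    def se(self, name: str) -> float:
        return self.standard_errors[name]

    def cov_submatrix(self, names: tuple[str, ...]) -> np.ndarray:
        idx = [self.model.free_params.index(n) for n in names]
        return self.covariance[np.ix_(idx, idx)]

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "params": {k: float(v) for k, v in self.params.items()},
            "fixed_params": {k: float(v) for k, v in self.model.fixed_params.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "covariance": self.covariance.tolist(),
            "free_params": list(self.model.free_params),
            "chi2_red": float(self.chi2_red),
            "dof": int(self.dof),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "message": self.message,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _bounds_arrays(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(len(spec.free_params), -np.inf)
    hi = np.full(len(spec.free_params), np.inf)
    for i, name in enumerate(spec.free_params):
        if name in spec.bounds:
            lo[i], hi[i] = spec.bounds[name]
    return lo, hi


def fit_model(
    spec: ModelSpec,
    x,
    y,
    y_err=None,
    init: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit ``spec`` to (x, y), optionally weighted by 1/y_err.

    Parameters
    ----------
    spec : ModelSpec
        Model function with free/fixed parameter declaration.
    x, y : array-like
        Equal-length series; at least ``len(free_params) + 1`` points.
    y_err : array-like, optional
        Per-point measurement standard errors (> 0).  Absent means unit
        weights with a-posteriori covariance scaling.
    init : mapping, optional
        Overrides for the data-driven default initialization.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D series")
    n = len(x)
    dof = n - len(spec.free_params)
    if dof <= 0:
        raise InputError(
            f"need more than {len(spec.free_params)} points for "
            f"{spec.name}, got {n}"
        )
    if y_err is not None:
        y_err = np.asarray(y_err, dtype=float)
        if y_err.shape != y.shape:
            raise InputError("y_err must match y in length")
        if np.any(~np.isfinite(y_err)) or np.any(y_err <= 0):
            raise InputError("y_err must be positive and finite")
        w = 1.0 / y_err
    else:
        w = np.ones_like(y)

    p0_map = dict(spec.default_init(x, y)) if spec.default_init else {}
    if init:
        p0_map.update(init)
    missing = [p for p in spec.free_params if p not in p0_map]
    if missing:
        raise InputError(f"no initial value for parameters {missing}")
    lo, hi = _bounds_arrays(spec)
    p0 = np.array([p0_map[p] for p in spec.free_params], dtype=float)
    p0 = np.clip(p0, lo + 0.0, hi)
    tiny = np.finfo(float).tiny
    p0[np.isfinite(lo) & (p0 <= lo)] = (lo + max(1e-9, tiny))[
        np.isfinite(lo) & (p0 <= lo)
    ]

    def resid(theta):
        kw = dict(zip(spec.free_params, theta))
        return w * (y - spec(x, **kw))

    try:
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        converged = bool(sol.success)
        message = sol.message
    except Exception as exc:  # pathological residuals, not user error
        sol = None
        converged = False
        message = str(exc)

    k = len(spec.free_params)
    if sol is None:
        params = dict(zip(spec.free_params, p0))
        cov = np.full((k, k), np.nan)
        ses = {p: np.nan for p in spec.free_params}
        return FitResult(spec, params, cov, ses, np.nan, dof,
                         np.full(n, np.nan), False, n, message)

    theta = sol.x
    res = sol.fun
    chi2 = float(res @ res)
    chi2_red = chi2 / dof

    # covariance from the Jacobian at the optimum: (J^T J)^-1,
    # rescaled by chi2_red when the weights were not true errors
    J = sol.jac
    JTJ = J.T @ J
    # a singular Jacobian (degenerate but possibly perfect fit) degrades the
    # covariance, not the convergence status
    try:
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JTJ)
        message += " (singular Jacobian; pseudo-inverse covariance)"
    if y_err is None:
        cov = cov * chi2_red
    cov = 0.5 * (cov + cov.T)

    params = dict(zip(spec.free_params, theta))
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    ses = dict(zip(spec.free_params, np.sqrt(diag)))
    return FitResult(
        model=spec,
        params=params,
        covariance=cov,
        standard_errors=ses,
        chi2_red=chi2_red,
        dof=dof,
        residuals=res,
        converged=converged,
        n_points=n,
        message=message,
    )
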