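"""The three trajectory models and their fit specifications.

All three models are unimodal or monotone curves whose location parameter
``mu`` carries the developmental timing information:

* ``lorentzian_model`` — the ecdysteroid pulse, a Cauchy-shaped peak with
  area ``A``, center ``mu`` and half-width-at-half-maximum ``sigma``;
* ``lognorm_model`` — the body-weight increase, an area-``A`` lognormal
  density in time whose mode sits at ``exp(mu - sigma**2)``;
* ``linked_linear_constant_model`` — the inter-wing distance, a linear
  rise ``b0 + b1*x`` blended into a plateau ``A`` by a logistic weight of
  fixed width ``sigma_link`` centered at ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

_SQRT2PI = np.sqrt(2.0 * np.pi)


def lognorm_model(x, A, mu, sigma):
    """Area-scaled lognormal density A * pdf_lognorm(x; mu, sigma).

    f(x) = A / (sigma * sqrt(2*pi)) * exp(-(ln x - mu)^2 / (2 sigma^2)) / x

    ``x`` must be strictly positive; ``mu`` and ``sigma`` are on the
    log-day scale.  The mode (peak location in time) is exp(mu - sigma^2)
    and the integral over (0, inf) is A.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("lognorm_model requires x > 0")
    if sigma <= 0:
        raise ValueError("lognorm_model requires sigma > 0")
    z = (np.log(x) - mu) / sigma
    return A / (sigma * _SQRT2PI) * np.exp(-0.5 * z * z) / x


def _logistic(a):
    # numerically stable 1/(1+exp(-a)) on both tails
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def linked_linear_constant_model(x, A, b0, b1, mu, sigma_link):
    """Linear branch blended into a constant plateau by a logistic link.

    f(x) = (b0 + b1*x) * (1 - L) + A * L,   L = 1/(1 + exp(-(x - mu)/sigma_link))

    The blend weight L crosses 1/2 exactly at ``mu``; f tends to the
    linear branch as x -> -inf and to the plateau A as x -> +inf.
    ``sigma_link`` sets the width of the link regime and is held fixed
    during fitting.
    """
    if sigma_link <= 0:
        raise ValueError("linked_linear_constant_model requires sigma_link > 0")
    x = np.asarray(x, dtype=float)
    L = _logistic((x - mu) / sigma_link)
    return (b0 + b1 * x) * (1.0 - L) + A * L


def lorentzian_model(x, A, mu, sigma):
    """Lorentzian (Cauchy) pulse with area A, center mu, HWHM sigma.

    f(x) = (A / pi) * sigma / ((x - mu)^2 + sigma^2)

    Peak value A/(pi*sigma) at x = mu; half maximum at x = mu +/- sigma.
    """
    if sigma <= 0:
        raise ValueError("lorentzian_model requires sigma > 0")
    x = np.asarray(x, dtype=float)
    d = x - mu
    return (A / np.pi) * sigma / (d * d + sigma * sigma)


@dataclass(frozen=True)
class ModelSpec:
    """A model function plus its fitting contract.

    ``free_params`` are estimated; ``fixed_params`` (e.g. the link width)
    are held at their given values.  ``default_init`` maps the data to
    starting values for the free parameters.
    """

    name: str
    func: Callable[..., np.ndarray]
    free_params: tuple[str, ...]
    fixed_params: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    default_init: Callable[[np.ndarray, np.ndarray], dict[str, float]] | None = None

    def __call__(self, x, **params):
        return self.func(x, **{**self.fixed_params, **params})

    def all_params(self) -> tuple[str, ...]:
        return self.free_params + tuple(self.fixed_params)


# ---------------------------------------------------------------------------
# default initialization rules (earliest time wins on ties)


def _init_lorentzian(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    i = int(np.argmax(y))  # argmax returns the first (earliest) maximum
    mu0 = float(x[i])
    span = float(np.ptp(x)) or 1.0
    sigma0 = span / 6.0
    peak = max(float(y[i]), np.finfo(float).tiny)
    return {"A": peak * np.pi * sigma0, "mu": mu0, "sigma": sigma0}


def _init_lognorm(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    # method of moments on the curve treated as a density in x
    w = np.clip(y, 0.0, None)
    tot = float(w.sum())
    if tot <= 0:
        return {"A": 1.0, "mu": float(np.log(np.median(x))), "sigma": 0.3}
    p = w / tot
    lx = np.log(x)
    mu0 = float(np.sum(p * lx))
    var0 = float(np.sum(p * (lx - mu0) ** 2))
    sigma0 = float(np.sqrt(max(var0, 1e-4)))
    area = float(np.trapezoid(w, x)) if len(x) > 1 else tot
    return {"A": max(area, np.finfo(float).tiny), "mu": mu0, "sigma": sigma0}


def _init_linked(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    # breakpoint guess: where the local slope drops the most
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    if len(xs) >= 3:
        d = np.diff(ys) / np.diff(xs)
        drops = d[1:] - d[:-1]
        j = int(np.argmin(drops))  # first (earliest) largest drop
        mu0 = float(xs[j + 1])
    else:
        mu0 = float(xs[len(xs) // 2])
    pre = xs <= mu0
    if pre.sum() >= 2:
        b1_0, b0_0 = np.polyfit(xs[pre], ys[pre], 1)
    else:
        b1_0 = (ys[-1] - ys[0]) / (xs[-1] - xs[0]) if xs[-1] > xs[0] else 0.0
        b0_0 = ys[0] - b1_0 * xs[0]
    return {"A": float(ys[-1]), "b0": float(b0_0), "b1": float(b1_0), "mu": mu0}


# ---------------------------------------------------------------------------
# spec factories


def lorentzian_spec() -> ModelSpec:
    return ModelSpec(
        name="lorentzian",
        func=lorentzian_model,
        free_params=("A", "mu", "sigma"),
        bounds={"sigma": (1e-9, np.inf)},
        default_init=_init_lorentzian,
    )


def lognorm_spec() -> ModelSpec:
    return ModelSpec(
        name="lognorm",
        func=lognorm_model,
        free_params=("A", "mu", "sigma"),
        bounds={"sigma": (1e-9, np.inf)},
        default_init=_init_lognorm,
    )


def linked_linear_constant_spec(sigma_link: float = 0.25) -> ModelSpec:
    """Linked linear/constant model; the link width is fixed, not fitted.

    The default width of 0.25 days keeps the transition regime well inside
    one daily sampling interval.
    """
    if sigma_link <= 0:
        raise ValueError("sigma_link must be > 0")
    return ModelSpec(
        name="linked_linear_constant",
        func=linked_linear_constant_model,
        free_params=("A", "b0", "b1", "mu"),
        fixed_params={"sigma_link": float(sigma_link)},
        default_init=_init_linked,
    )


def lognorm_increase_spec(x_ref: float) -> ModelSpec:
    """Lognormal trajectory of the increase relative to a reference time.

    f(x) = lognorm(x) - lognorm(x_ref), the correctly specified model for
    data recorded as "increase since the first sampled day".  Same free
    parameters (A, mu, sigma) as the plain lognormal; the weight-peak
    milestone is still the lognormal mode exp(mu - sigma^2).
    """
    if x_ref <= 0:
        raise ValueError("x_ref must be > 0")

    def func(x, A, mu, sigma):
        return lognorm_model(x, A, mu, sigma) - lognorm_model(x_ref, A, mu, sigma)

    return ModelSpec(
        name="lognorm_increase",
        func=func,
        free_params=("A", "mu", "sigma"),
        fixed_params={},
        bounds={"sigma": (1e-9, np.inf)},
        default_init=_init_lognorm,
    )


MODEL_SPECS: dict[str, Callable[..., ModelSpec]] = {
    "lorentzian": lorentzian_spec,
    "lognorm": lognorm_spec,
    "linked_linear_constant": linked_linear_constant_spec,
}
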