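"""Constrained logistic growth model and derived growth metrics.

The population trajectory is modelled as logistic growth under limited
resources,

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t)),

with carrying capacity K (signal units), initial population N0 = N(0) and
growth rate r (per hour), all constrained positive.  The fit minimises the
sum of squared residuals against the preprocessed curve, starting from

    K0  = max of the curve,
    N00 = min of the curve,
    r0  = ln((K0 - N00) / N00) / mu,

where mu is the empirical maximum-slope time of the data.  From the fitted
model the maximum-slope time (the inflection, where N = K/2), the maximum
growth rate rK/4, and a tangent-construction lag time are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .preprocess import CurveId, GrowthCurve

__all__ = [
    "LogisticFit",
    "GrowthMetrics",
    "logistic_eval",
    "empirical_max_slope_time",
    "init_parameters",
    "fit_logistic",
    "max_slope_time",
    "lag_time",
    "compute_metrics",
]

#: lower box bound enforcing positivity of K, N0, r
POSITIVE_LB = 1e-12


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters and diagnostics for one curve."""

    K: float
    N0: float
    r: float
    sse: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.N0 > 0 and self.r > 0):
            raise ValueError("K, N0 and r must all be positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")

    @property
    def has_interior_inflection(self) -> bool:
        """True when the inflection lies at t > 0, i.e. K > 2 N0."""
        return self.K > 2.0 * self.N0


@dataclass(frozen=True)
class GrowthMetrics:
    """Scalar growth characteristics derived from one fitted curve.

    ``max_slope_time`` is the model's inflection time (hours); ``lag_time``
    comes from intersecting the inflection tangent with N = N0;
    ``max_growth_rate`` is the slope at the inflection, rK/4.
    """

    curve_id: CurveId
    max_slope_time: float
    lag_time: float
    max_growth_rate: float
    carrying_capacity: float
    empirical_max_slope_time: float
    fit: LogisticFit
    stages: tuple[str, ...] = ()


def logistic_eval(
    K: float, N0: float, r: float, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Evaluate N(t) = K / (1 + ((K - N0)/N0) exp(-r t)).

    For K, N0, r > 0 and t >= 0 the denominator is bounded below by
    min(1, K/N0) > 0, so the expression is well defined even when N0 > K.
    """
    if not (K > 0 and N0 > 0 and r > 0):
        raise ValueError(f"K, N0, r must be positive, got K={K}, N0={N0}, r={r}")
    t = np.asarray(t, dtype=float)
    out = K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def _slope_argmax(times: np.ndarray, values: np.ndarray) -> tuple[float, bool]:
    slopes = np.diff(values) / np.diff(times)
    i = int(np.argmax(slopes))  # ties -> earliest interval
    degenerate = bool(np.all(slopes == slopes[0]) and slopes[0] <= 0)
    if degenerate:
        i = 0
    return float(0.5 * (times[i] + times[i + 1])), degenerate


def empirical_max_slope_time(curve: Union[GrowthCurve, Sequence[float]], times=None) -> float:
    """Midpoint of the interval with the steepest forward-difference slope.

    Ties are broken by the earliest interval; a flat curve (all slopes equal
    and non-positive) yields the first midpoint with a warning.
    """
    if isinstance(curve, GrowthCurve):
        t, v = curve.times, curve.values
    else:
        if times is None:
            raise TypeError("times required when passing a bare value sequence")
        v = np.asarray(curve, dtype=float)
        t = np.asarray(times, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points")
    mu, degenerate = _slope_argmax(t, v)
    if degenerate:
        warnings.warn("no rising segment: empirical maximum-slope time is degenerate", stacklevel=2)
    return mu


def init_parameters(curve: GrowthCurve) -> tuple[float, float, float]:
    """Starting values (K0, N00, r0) for the least-squares fit.

    K0 and N00 are the curve's maximum and minimum; r0 solves the logistic
    inflection relation at the empirical maximum-slope time mu,
    r0 = ln((K0 - N00)/N00) / mu.  A non-positive minimum (possible after
    baseline subtraction and smoother undershoot) cannot seed a
    positivity-constrained model, so N00 is then replaced by the curve's
    smallest positive value; where the rate expression is undefined
    ((K0 - N00)/N00 <= 1 or mu <= 0) the fallback r0 = 1 / (time span)
    keeps the optimiser in a sane rate regime.
    """
    v = curve.values
    K0 = float(np.max(v))
    N00 = float(np.min(v))
    if K0 <= N00:
        raise ValueError(f"curve {curve.curve_id}: no growth signal (max equals min)")
    if N00 <= 0:
        positive = v[v > 0]
        N00 = float(np.min(positive)) if positive.size else K0 * 1e-6
    span = float(curve.times[-1] - curve.times[0])
    mu = empirical_max_slope_time(curve)
    if (K0 - N00) / N00 > 1.0 and mu > 0:
        r0 = float(np.log((K0 - N00) / N00) / mu)
    else:
        r0 = 1.0 / span
    return K0, max(N00, POSITIVE_LB), r0


def fit_logistic(curve: GrowthCurve, *, truncate_at_peak: bool = False) -> LogisticFit:
    """Least-squares logistic fit with positivity constraints.

    Minimises sum_t (N(t; K, N0, r) - value_t)^2 over K, N0, r > 0
    (box lower bound 1e-12) from :func:`init_parameters`, using a
    trust-region reflective solver with function tolerance 1e-10 and at
    most 10^4 evaluations.  On non-convergence the best-found parameters
    are still returned, flagged via ``converged``.

    ``truncate_at_peak`` drops all points after the curve's global maximum
    before fitting — an option for nephelometric curves whose post-peak
    decline the monotone logistic cannot represent; the default fits
    through the full trace.
    """
    if len(curve) < 5:
        raise ValueError(f"curve {curve.curve_id}: need >= 5 points to fit")
    t, v = curve.times, curve.values
    if truncate_at_peak:
        i_max = int(np.argmax(v))
        if i_max >= 4:  # keep at least 5 points
            t, v = t[: i_max + 1], v[: i_max + 1]
        work = GrowthCurve(curve.curve_id, t, v, curve.stages)
    else:
        work = curve

    K0, N00, r0 = init_parameters(work)

    def residuals(p: np.ndarray) -> np.ndarray:
        K, N0, r = p
        return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t)) - v

    res = least_squares(
        residuals,
        x0=np.array([K0, N00, r0]),
        bounds=(np.full(3, POSITIVE_LB), np.full(3, np.inf)),
        method="trf",
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=10_000,
    )
    K, N0, r = (float(x) for x in res.x)
    return LogisticFit(
        K=K,
        N0=N0,
        r=r,
        sse=float(np.sum(res.fun**2)),
        converged=bool(res.success),
        n_points=len(t),
    )


def max_slope_time(fit: LogisticFit) -> float:
    """Inflection time of the fitted logistic, ln((K - N0)/N0) / r.

    When K <= 2 N0 the inflection would lie at t <= 0; over the observable
    range t >= 0 the slope is then maximal at t = 0, which is returned
    (``fit.has_interior_inflection`` distinguishes the two cases).
    """
    if not fit.has_interior_inflection:
        return 0.0
    return float(np.log((fit.K - fit.N0) / fit.N0) / fit.r)


def lag_time(fit: LogisticFit) -> float:
    """Lag duration from the classical tangent-at-inflection construction.

    The tangent to N(t) at the inflection (slope rK/4, value K/2) is
    intersected with the horizontal line N = N0; the crossing time

        t_lag = mu - 2/r + 4 N0 / (r K),   mu = max_slope_time(fit),

    is the lag estimate, clipped below at 0.  Fits without an interior
    inflection (K <= 2 N0) have no lag phase and return 0.
    """
    if not fit.has_interior_inflection:
        return 0.0
    mu = max_slope_time(fit)
    t_lag = mu - 2.0 / fit.r + 4.0 * fit.N0 / (fit.r * fit.K)
    return float(max(t_lag, 0.0))


def compute_metrics(fit: LogisticFit, curve: GrowthCurve) -> GrowthMetrics:
    """Bundle the derived scalars for one fitted curve."""
    return GrowthMetrics(
        curve_id=curve.curve_id,
        max_slope_time=max_slope_time(fit),
        lag_time=lag_time(fit),
        max_growth_rate=fit.r * fit.K / 4.0,
        carrying_capacity=fit.K,
        empirical_max_slope_time=empirical_max_slope_time(curve),
        fit=fit,
        stages=curve.stages,
    )
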