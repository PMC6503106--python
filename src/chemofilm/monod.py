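"""Monod growth kinetics.

The specific growth rate of a microbial population limited by a single
substrate is modelled by the hyperbolic Monod function

    mu(S) = mu_max * S / (Ks + S)

where ``mu_max`` (h^-1) is the maximum specific growth rate and ``Ks`` is the
saturation constant, the substrate concentration supporting half-maximal
growth.  Substrate concentrations throughout this package are expressed as
fractions of the full-strength growth medium (1.0 = undiluted), so ``Ks``
shares that unit.

This module provides the rate law itself, the exponential-growth calculus on
timed density series (specific growth rate between two readings, maximum
log-linear slope over a sliding window), and estimation of ``(mu_max, Ks)``
from paired (substrate, rate) observations via the classical
double-reciprocal (Lineweaver-Burk) line, with an optional nonlinear
least-squares refinement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import EstimationError

__all__ = [
    "MonodParameters",
    "GrowthObservation",
    "TimedDensitySeries",
    "monod_rate",
    "specific_growth_rate",
    "max_specific_growth_rate",
    "doubling_time",
    "MonodCurveFit",
    "fit_monod",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonodParameters:
    """Kinetic constants for one strain/substrate pair.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate, h^-1.
    Ks : float
        Saturation constant, in fractions of full-strength medium.
    Y : float, default 0.4
        Yield coefficient (biomass produced per unit substrate consumed),
        dimensionless, in (0, 1].
    """

    mu_max: float
    Ks: float
    Y: float = 0.4

    def __post_init__(self) -> None:
        if not (self.mu_max > 0):
            raise ValueError(f"mu_max must be positive, got {self.mu_max}")
        if not (self.Ks > 0):
            raise ValueError(f"Ks must be positive, got {self.Ks}")
        if not (0 < self.Y <= 1):
            raise ValueError(f"Y must be in (0, 1], got {self.Y}")

    def rate(self, S):
        """Monod growth rate at substrate concentration ``S``."""
        return monod_rate(S, self)


class GrowthObservation(NamedTuple):
    """One point on the saturation curve: substrate concentration and the
    specific growth rate it supports."""

    S: float
    mu: float


@dataclass(frozen=True)
class TimedDensitySeries:
    """Time-stamped biomass-proxy readings from one batch culture.

    ``times`` are hours (strictly increasing), ``values`` are strictly
    positive optical densities or cell densities.  ``dilution`` optionally
    labels the medium strength (fraction of full-strength) the culture grew in.
    """

    times: np.ndarray
    values: np.ndarray
    dilution: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a density series needs at least 2 points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(values > 0):
            raise ValueError("density values must be strictly positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size


def monod_rate(S, params: MonodParameters):
    """Specific growth rate mu(S) = mu_max * S / (Ks + S).

    Accepts scalars or arrays; strictly increasing in ``S`` and bounded above
    by ``mu_max``.  Raises :class:`ValueError` for negative substrate.
    """
    arr = np.asarray(S, dtype=float)
    if np.any(arr < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = params.mu_max * arr / (params.Ks + arr)
    return float(out) if arr.ndim == 0 else out


def specific_growth_rate(x1: float, t1: float, x2: float, t2: float) -> float:
    """Exponential-growth rate between two density readings.

    Returns ``ln(x2/x1) / (t2 - t1)`` in h^-1; negative when the population
    declines.
    """
    if x1 <= 0 or x2 <= 0:
        raise ValueError("densities must be strictly positive")
    if t2 <= t1:
        raise ValueError("t2 must be later than t1")
    return math.log(x2 / x1) / (t2 - t1)


def max_specific_growth_rate(series: TimedDensitySeries, window: int = 3) -> float:
    """Maximum log-linear growth rate over a sliding window.

    Fits an ordinary least-squares line to ln(value) vs time inside every run
    of ``window`` consecutive points and returns the largest slope.  The
    default window of 3 points spans two sampling intervals, damping read
    noise relative to two-point increments.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 points")
    n = len(series)
    if n < window:
        raise ValueError(f"series has {n} points, shorter than window {window}")
    log_values = np.log(series.values)
    best = -math.inf
    for i in range(n - window + 1):
        slope = np.polyfit(series.times[i : i + window], log_values[i : i + window], 1)[0]
        best = max(best, float(slope))
    return best


def doubling_time(mu: float) -> float:
    """Population doubling time ln(2)/mu, hours."""
    if mu <= 0:
        raise ValueError("growth rate must be positive for a doubling time")
    return math.log(2.0) / mu


def _as_xy(S, mu):
    """Coerce fit inputs to flat float arrays.

    Accepts (S, mu) arrays, a 2-D sklearn-style design matrix with one
    column, or a sequence of (S, mu) pairs / GrowthObservation with mu=None.
    """
    if mu is None:
        pairs = np.asarray([(obs[0], obs[1]) for obs in S], dtype=float)
        if pairs.size == 0:
            raise EstimationError("no observations supplied")
        return pairs[:, 0], pairs[:, 1]
    S = np.asarray(S, dtype=float)
    if S.ndim == 2:
        if S.shape[1] != 1:
            raise ValueError("substrate design matrix must have a single column")
        S = S[:, 0]
    mu = np.asarray(mu, dtype=float).ravel()
    if S.shape != mu.shape:
        raise ValueError("S and mu must have the same length")
    return S, mu


class MonodCurveFit(RegressorMixin, BaseEstimator):
    """Estimator for Monod kinetic constants from (S, mu) observations.

    Parameters
    ----------
    method : {"reciprocal", "nls"}, default "reciprocal"
        "reciprocal" fits the double-reciprocal line 1/mu = 1/mu_max +
        (Ks/mu_max)/S by unweighted ordinary least squares.  "nls" refines
        that estimate by nonlinear least squares on the Monod curve itself,
        which weights observations more evenly (the reciprocal transform
        over-weights low-rate points).
    Y : float, default 0.4
        Yield coefficient carried through to the fitted
        :class:`MonodParameters`; it is never estimated here.

    Attributes
    ----------
    mu_max_ : float
        Estimated maximum specific growth rate, h^-1.
    Ks_ : float
        Estimated saturation constant.
    params_ : MonodParameters
        The fitted constants bundled with ``Y``.
    n_points_ : int
        Number of observations used after excluding S = 0 or mu = 0.
    n_excluded_ : int
        Number of observations dropped (undefined reciprocals).
    r_squared_ : float
        Coefficient of determination of the fit (reciprocal space for
        "reciprocal", rate space for "nls").
    """

    def __init__(self, method: str = "reciprocal", Y: float = 0.4):
        self.method = method
        self.Y = Y

    def fit(self, S, mu=None):
        if self.method not in ("reciprocal", "nls"):
            raise ValueError(f"unknown method {self.method!r}")
        S, mu = _as_xy(S, mu)
        usable = (S > 0) & (mu > 0)
        n_excluded = int(np.sum(~usable))
        if n_excluded:
            logger.info("excluding %d observation(s) with S = 0 or mu = 0", n_excluded)
        S, mu = S[usable], mu[usable]
        if S.size < 2 or np.unique(S).size < 2:
            raise EstimationError(
                "need at least 2 observations at distinct positive S with positive mu"
            )

        inv_S, inv_mu = 1.0 / S, 1.0 / mu
        slope, intercept = np.polyfit(inv_S, inv_mu, 1)
        if intercept <= 0 or slope <= 0:
            raise EstimationError(
                "double-reciprocal fit produced non-positive intercept or slope "
                f"(intercept={intercept:.4g}, slope={slope:.4g}); the data do not "
                "resemble a saturating curve"
            )
        mu_max = 1.0 / intercept
        Ks = slope / intercept

        if self.method == "nls":
            from scipy.optimize import curve_fit

            (mu_max, Ks), _ = curve_fit(
                lambda s, m, k: m * s / (k + s),
                S,
                mu,
                p0=(mu_max, Ks),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
            )
            if mu_max <= 0 or Ks <= 0:
                raise EstimationError("nonlinear refit produced non-positive estimates")
            fitted = mu_max * S / (Ks + S)
            ss_res = float(np.sum((mu - fitted) ** 2))
            ss_tot = float(np.sum((mu - mu.mean()) ** 2))
        else:
            fitted_inv = intercept + slope * inv_S
            ss_res = float(np.sum((inv_mu - fitted_inv) ** 2))
            ss_tot = float(np.sum((inv_mu - inv_mu.mean()) ** 2))

        self.mu_max_ = float(mu_max)
        self.Ks_ = float(Ks)
        self.params_ = MonodParameters(self.mu_max_, self.Ks_, self.Y)
        self.n_points_ = int(S.size)
        self.n_excluded_ = n_excluded
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, S):
        if not hasattr(self, "params_"):
            raise EstimationError("estimator is not fitted")
        arr = np.asarray(S, dtype=float)
        if arr.ndim == 2:
            arr = arr[:, 0]
        return monod_rate(arr, self.params_)

    def fit_report(self) -> dict:
        """Summary of the fit as a plain dict (for CSV/JSON export)."""
        if not hasattr(self, "params_"):
            raise EstimationError("estimator is not fitted")
        return {
            "mu_max": self.mu_max_,
            "Ks": self.Ks_,
            "method": self.method,
            "n_points": self.n_points_,
            "r_squared": self.r_squared_,
        }


def fit_monod(S, mu=None, method: str = "reciprocal", Y: float = 0.4) -> MonodParameters:
    """Fit Monod constants; thin wrapper over :class:`MonodCurveFit`.

    ``S`` may be an array of substrate concentrations paired with ``mu``, or a
    sequence of :class:`GrowthObservation` (with ``mu`` omitted).
    """
    return MonodCurveFit(method=method, Y=Y).fit(S, mu).params_
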