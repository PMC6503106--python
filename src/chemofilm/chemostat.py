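"""Closed-form chemostat steady states (Novick-Szilard model).

A chemostat dilutes a well-mixed culture at rate ``D`` (h^-1) with medium
carrying limiting substrate at concentration ``Sr``.  At steady state the
suspended (planktonic) population grows exactly as fast as it is washed out,
mu(S) = D, which pins the residual substrate at

    S_bar(D) = Ks * D / (mu_max - D)

independently of ``Sr`` and of the biomass itself.  The biomass follows from
the yield coefficient, X_bar = Y * (Sr - S_bar), and the harvestable
production is P = D * X_bar.  A positive steady state exists only below the
critical dilution rate D_crit = mu(Sr); at or above it the culture washes
out (X_bar = 0, S_bar = Sr).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import WashoutError
from .monod import MonodParameters, monod_rate

__all__ = [
    "ChemostatConfig",
    "SteadyState",
    "DilutionSweep",
    "steady_state_substrate",
    "critical_dilution_rate",
    "steady_state",
    "optimal_dilution_rate",
    "production_ratio_table",
    "sweep",
]


@dataclass(frozen=True)
class ChemostatConfig:
    """One chemostat operating point: inflow substrate, dilution rate, kinetics.

    ``volume_ml`` is metadata only (the bench-scale vessel this package's
    reference dataset came from held 57 mL); it enters no computation.
    """

    Sr: float
    D: float
    params: MonodParameters
    volume_ml: float = 57.0

    def __post_init__(self) -> None:
        if self.Sr < 0:
            raise ValueError("inflow substrate concentration Sr must be >= 0")
        if self.D < 0:
            raise ValueError("dilution rate D must be >= 0")


@dataclass(frozen=True)
class SteadyState:
    """Predicted steady state at one dilution rate.

    ``residence_time`` (1/D, hours) is ``None`` at D = 0.  Under washout the
    state is well-formed with S_bar = Sr, X_bar = 0, P = 0.
    """

    D: float
    S_bar: float
    X_bar: float
    P: float
    washout: bool
    residence_time: float | None


def steady_state_substrate(D: float, params: MonodParameters) -> float:
    """Residual substrate at steady state, Ks*D/(mu_max - D).

    Strictly increasing in ``D`` and -> 0 as D -> 0.  Raises
    :class:`WashoutError` for D >= mu_max, where no planktonic steady state
    exists at any inflow concentration.
    """
    if D < 0:
        raise ValueError("dilution rate must be non-negative")
    if D >= params.mu_max:
        raise WashoutError(
            f"D = {D} h^-1 >= mu_max = {params.mu_max} h^-1: washout at any Sr"
        )
    return params.Ks * D / (params.mu_max - D)


def critical_dilution_rate(Sr: float, params: MonodParameters) -> float:
    """Washout bound mu(Sr) = mu_max*Sr/(Ks + Sr).

    The supremum of dilution rates admitting positive planktonic biomass when
    fed substrate at concentration ``Sr``.
    """
    if Sr <= 0:
        raise ValueError("Sr must be positive")
    return monod_rate(Sr, params)


def steady_state(config: ChemostatConfig) -> SteadyState:
    """Closed-form steady state for one operating point.

    Dilution rates at or above the critical rate yield a washout state
    (the bound itself is classified as washout, since the positive branch
    exists only strictly below it).
    """
    D, Sr, params = config.D, config.Sr, config.params
    residence = 1.0 / D if D > 0 else None
    D_crit = critical_dilution_rate(Sr, params) if Sr > 0 else 0.0
    if D >= D_crit and D > 0:
        # includes D >= mu_max; the bound itself counts as washout
        return SteadyState(D, Sr, 0.0, 0.0, True, residence)
    S_bar = steady_state_substrate(D, params)
    X_bar = params.Y * (Sr - S_bar)
    P = D * X_bar
    return SteadyState(D, S_bar, X_bar, P, False, residence)


def optimal_dilution_rate(Sr: float, params: MonodParameters) -> float:
    """Dilution rate maximising production, mu_max*(1 - sqrt(Ks/(Ks+Sr)))."""
    if Sr <= 0:
        raise ValueError("Sr must be positive")
    return params.mu_max * (1.0 - math.sqrt(params.Ks / (params.Ks + Sr)))


def production_ratio_table(configs: Sequence[ChemostatConfig]) -> pd.DataFrame:
    """Production per operating point, normalised to the best of the set.

    All configs must share kinetic parameters and inflow concentration; the
    result has columns ``D``, ``P`` and ``pct_of_max`` (integer percent).
    If every point washes out, percentages are all zero and a warning is
    issued.
    """
    if len(configs) == 0:
        raise ValueError("need at least one config")
    ref = configs[0]
    for c in configs[1:]:
        if c.params != ref.params or c.Sr != ref.Sr:
            raise ValueError("configs must share params and Sr")
    states = [steady_state(c) for c in configs]
    P = np.array([s.P for s in states])
    P_max = P.max()
    if P_max <= 0:
        warnings.warn("all operating points wash out; production shares are zero")
        pct = np.zeros_like(P, dtype=int)
    else:
        pct = np.array([int(round(100.0 * p / P_max)) for p in P])
    return pd.DataFrame({"D": [c.D for c in configs], "P": P, "pct_of_max": pct})


@dataclass(frozen=True)
class DilutionSweep:
    """Steady states evaluated over an ascending dilution-rate grid."""

    D_grid: np.ndarray
    states: tuple
    base: ChemostatConfig

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "D": [s.D for s in self.states],
                "S_bar": [s.S_bar for s in self.states],
                "X_bar": [s.X_bar for s in self.states],
                "P": [s.P for s in self.states],
                "washout": [s.washout for s in self.states],
                "residence_time_h": [
                    s.residence_time if s.residence_time is not None else np.nan
                    for s in self.states
                ],
            }
        )

    def at(self, D: float) -> SteadyState:
        """Marker extraction: the steady state at an arbitrary dilution rate."""
        return steady_state(replace(self.base, D=float(D)))


def sweep(base: ChemostatConfig, D_grid) -> DilutionSweep:
    """Evaluate steady states along ``D_grid`` (strictly increasing, >= 0)."""
    grid = np.asarray(D_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("D_grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("D_grid must be strictly increasing")
    if grid[0] < 0:
        raise ValueError("dilution rates must be non-negative")
    states = tuple(steady_state(replace(base, D=float(D))) for D in grid)
    return DilutionSweep(grid, states, base)
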