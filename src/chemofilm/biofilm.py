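"""Biofilm accumulation inference from timed surface cell counts.

Surface-attached cells in a chemostat are exposed to the steady-state
substrate level set by the suspended population but are not themselves
diluted, so their net accumulation over a timed slide exposure is treated as
exponential, N(t) = N0 * exp(mu * t).  Given the final density of the
sparsest assay — a dispersed monolayer assumed to grow at the plankton rate,
i.e. at the dilution rate — the initial attached density N0 is back-
calculated, and that single N0 anchors the growth-rate estimates of the
denser assays.

The module also classifies flow regimes: below ~4 h^-1 the dilution rate
itself governs biofilm buildup through substrate availability; far above it
only shear stress matters (roughly 0.01-0.04 Pa permits buildup, >= 1 Pa
strips biofilm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .chemostat import ChemostatConfig, production_ratio_table
from .monod import MonodParameters, doubling_time

__all__ = [
    "BiofilmObservation",
    "BiofilmGrowthEstimate",
    "FlowDomainResult",
    "back_calculate_initial_density",
    "BiofilmGrowthModel",
    "biofilm_growth_rates",
    "fold_change",
    "classify_flow_domain",
    "summarize_assays",
]

#: Dilution rate (h^-1) below which flow enhances biofilm buildup via
#: substrate supply; roughly the fastest known prokaryotic growth rate.
SLOW_FLOW_MAX_D = 4.0
#: Dilution rate (h^-1) above which only shear stress governs attachment
#: (an order of magnitude beyond the slow-flow bound; reported flow-cell
#: systems run at ~19-260 h^-1).
FAST_FLOW_MIN_D = 40.0
#: Shear stress (Pa) at or below which biofilm buildup is permitted.
SHEAR_BUILDUP_MAX_PA = 0.04
#: Shear stress (Pa) at or above which biofilms are generally destroyed.
SHEAR_DESTRUCTIVE_MIN_PA = 1.0


@dataclass(frozen=True)
class BiofilmObservation:
    """Summary of attached-cell counts at one dilution rate.

    ``mean_density`` / ``sd_density`` are cells cm^-2 over ``n_stacks``
    confocal image stacks after ``exposure_h`` hours of slide exposure;
    ``sd_density`` may be None when unreported.  ``nonviable_fraction`` is
    the membrane-compromised share of the total count; it never enters
    growth-rate estimates (the total count does).
    """

    D: float
    exposure_h: float
    mean_density: float
    sd_density: float | None = None
    n_stacks: int = 1
    nonviable_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("dilution rate must be non-negative")
        if self.exposure_h <= 0:
            raise ValueError("exposure time must be positive")
        if self.mean_density <= 0:
            raise ValueError("mean density must be positive")
        if self.n_stacks < 1:
            raise ValueError("need at least one image stack")
        if not (0 <= self.nonviable_fraction <= 1):
            raise ValueError("nonviable_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BiofilmGrowthEstimate:
    """Inferred biofilm kinetics for one assay."""

    D: float
    X0: float
    mu_biofilm: float
    reference_D: float


@dataclass(frozen=True)
class FlowDomainResult:
    """Flow-regime classification; ``shear_note`` is None without shear data."""

    domain: str
    shear_note: str | None = None


def back_calculate_initial_density(final_density: float, mu: float, t: float) -> float:
    """Initial attached density implied by exponential growth at rate ``mu``.

    Inverts N(t) = N0 * exp(mu*t): returns ``final_density * exp(-mu*t)``.
    """
    if final_density <= 0:
        raise ValueError("final density must be positive")
    if t <= 0:
        raise ValueError("exposure time must be positive")
    return final_density * math.exp(-mu * t)


class BiofilmGrowthModel(BaseEstimator):
    """Estimator for biofilm growth rates anchored on a reference assay.

    Parameters
    ----------
    reference_D : float or None, default None
        Dilution rate of the assay whose biofilm is assumed to grow at the
        plankton rate (mu = D); None selects the lowest supplied D, the
        sparse-monolayer assay, which is the only one plausibly growing at
        the ambient-substrate rate throughout the exposure.

    Attributes
    ----------
    X0_ : float
        Initial attached density (cells cm^-2) back-calculated from the
        reference assay.
    estimates_ : tuple of BiofilmGrowthEstimate
        Per-assay inferred rates; the reference assay's rate equals its
        dilution rate by construction.
    """

    def __init__(self, reference_D: float | None = None):
        self.reference_D = reference_D

    def fit(self, observations: Sequence[BiofilmObservation], y=None):
        obs = list(observations)
        if not obs:
            raise ValueError("no observations supplied")
        exposures = {o.exposure_h for o in obs}
        if len(exposures) != 1:
            raise ValueError("all observations must share the exposure time")
        ref_D = self.reference_D if self.reference_D is not None else min(o.D for o in obs)
        refs = [o for o in obs if o.D == ref_D]
        if not refs:
            raise ValueError(f"no observation at reference_D = {ref_D}")
        ref = refs[0]
        X0 = back_calculate_initial_density(ref.mean_density, ref.D, ref.exposure_h)
        self.X0_ = X0
        self.reference_D_ = float(ref_D)
        self.estimates_ = tuple(
            BiofilmGrowthEstimate(
                D=o.D,
                X0=X0,
                mu_biofilm=math.log(o.mean_density / X0) / o.exposure_h,
                reference_D=float(ref_D),
            )
            for o in obs
        )
        return self

    def predict(self, exposure_h) -> np.ndarray:
        """Projected total density of each fitted assay after ``exposure_h`` hours."""
        if not hasattr(self, "estimates_"):
            raise ValueError("model is not fitted")
        t = np.asarray(exposure_h, dtype=float)
        mus = np.array([e.mu_biofilm for e in self.estimates_])
        return self.X0_ * np.exp(np.multiply.outer(t, mus))


def biofilm_growth_rates(
    observations: Sequence[BiofilmObservation], reference_D: float | None = None
) -> list[BiofilmGrowthEstimate]:
    """Per-assay biofilm growth rates; wrapper over :class:`BiofilmGrowthModel`."""
    return list(BiofilmGrowthModel(reference_D=reference_D).fit(observations).estimates_)


def fold_change(a: float, b: float) -> float:
    """Dimensionless ratio a/b; ``b`` must be positive."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


def classify_flow_domain(
    D: float,
    shear_Pa: float | None = None,
    slow_max: float = SLOW_FLOW_MAX_D,
    fast_min: float = FAST_FLOW_MIN_D,
) -> FlowDomainResult:
    """Assign a dilution rate to the slow / intermediate / fast flow domain.

    ``slow``: D < ``slow_max``, where dilution rate enhances buildup;
    ``fast``: D > ``fast_min``, where shear stress alone governs attachment;
    ``intermediate`` otherwise (both boundaries inclusive to intermediate —
    the bound between intermediate and fast is a convention, since only
    "substantially above" the slow bound is physically specified).  When
    shear stress is supplied, a note marks it destructive (>= 1 Pa) or
    buildup-permissive (<= 0.04 Pa); in between no note is emitted.
    """
    if D < 0:
        raise ValueError("dilution rate must be non-negative")
    if shear_Pa is not None and shear_Pa < 0:
        raise ValueError("shear stress must be non-negative")
    if D < slow_max:
        domain = "slow"
    elif D > fast_min:
        domain = "fast"
    else:
        domain = "intermediate"
    note = None
    if shear_Pa is not None:
        if shear_Pa >= SHEAR_DESTRUCTIVE_MIN_PA:
            note = "destructive"
        elif shear_Pa <= SHEAR_BUILDUP_MAX_PA:
            note = "buildup-permissive"
    return FlowDomainResult(domain, note)


def summarize_assays(
    observations: Sequence[BiofilmObservation],
    reference_D: float | None = None,
    params: MonodParameters | None = None,
    Sr: float | None = None,
) -> pd.DataFrame:
    """Per-assay report combining measured counts with theory.

    One row per observation (sorted by D): plankton doubling time ln2/D,
    percent of mu_max, measured cells cm^-2, the inferred initial density
    (reported on the reference row only — elsewhere it is an anchor, not an
    observation), the inferred biofilm growth rate, the non-viable
    percentage, and (when ``params`` and ``Sr`` are given) each rate's
    planktonic production as a percent of the best of the set.
    """
    obs = sorted(observations, key=lambda o: o.D)
    columns = [
        "D",
        "doubling_time_h",
        "pct_mu_max",
        "cells_per_cm2",
        "initial_density_per_cm2",
        "mu_biofilm",
        "nonviable_pct",
        "pct_highest_P",
    ]
    if not obs:
        return pd.DataFrame(columns=columns)
    estimates = biofilm_growth_rates(obs, reference_D=reference_D)
    ref_D = estimates[0].reference_D
    if params is not None and Sr is not None:
        configs = [ChemostatConfig(Sr=Sr, D=o.D, params=params) for o in obs]
        pct_P = production_ratio_table(configs)["pct_of_max"].to_numpy(dtype=float)
    else:
        pct_P = np.full(len(obs), np.nan)
    rows = []
    for o, e, p in zip(obs, estimates, pct_P):
        rows.append(
            {
                "D": o.D,
                "doubling_time_h": doubling_time(o.D) if o.D > 0 else np.nan,
                "pct_mu_max": 100.0 * o.D / params.mu_max if params is not None else np.nan,
                "cells_per_cm2": o.mean_density,
                "initial_density_per_cm2": e.X0 if o.D == ref_D else np.nan,
                "mu_biofilm": e.mu_biofilm,
                "nonviable_pct": 100.0 * o.nonviable_fraction,
                "pct_highest_P": p,
            }
        )
    return pd.DataFrame(rows, columns=columns)
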