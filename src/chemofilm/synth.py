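"""Synthetic data generators.

Forward models with known ground truth for every inference stage in the
package: batch dilution-series growth curves (the closed-vessel limit of the
chemostat ODEs), chemostat time series, and biofilm stack-count replicates
(exponential accumulation with between-stack scatter).  All generators are
pure functions of their spec and seed, so a fixed seed reproduces output
byte-for-byte.

Noise is multiplicative lognormal throughout — biomass proxies are strictly
positive and their scatter scales roughly with signal — parameterised by a
coefficient of variation and mean-corrected so the noisy values are unbiased
around the noiseless curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .biofilm import BiofilmObservation
from .chemostat import ChemostatConfig
from .datasets import REFERENCE_PARAMS
from .dynamics import Trajectory, simulate
from .monod import MonodParameters, TimedDensitySeries

__all__ = [
    "SyntheticSpec",
    "gen_batch_series",
    "gen_biofilm_counts",
    "gen_chemostat_series",
]

#: TSB dilution series used for the batch growth curves: halved at each step,
#: with 1/32 omitted (that culture was not usable in the bench series).
DEFAULT_DILUTIONS = (1.0, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 64, 1 / 128)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and sampling design for the generators.

    ``noise_cv`` applies to optical-density readings (default 5%);
    ``stack_cv`` to per-stack biofilm counts (default 20%, image counts
    scatter far more than bulk OD).  ``inoculum`` is the batch starting
    biomass in substrate-equivalent units.  ``batch_duration_h`` covers the
    full growth phase of even the slowest (most dilute) culture at 30-min
    readings.
    """

    params: MonodParameters = REFERENCE_PARAMS
    dilutions: tuple = DEFAULT_DILUTIONS
    sampling_interval_h: float = 0.5
    batch_duration_h: float = 12.0
    inoculum: float = 1e-4
    noise_cv: float = 0.05
    stack_cv: float = 0.2
    n_stacks: tuple = (7, 7, 4)
    exposure_h: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0 < d <= 1) for d in self.dilutions):
            raise ValueError("dilutions must lie in (0, 1]")
        if self.noise_cv < 0 or self.stack_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.inoculum <= 0:
            raise ValueError("inoculum must be positive")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(0.0, np.sqrt(sigma2), size) - sigma2 / 2.0)


def gen_batch_series(spec: SyntheticSpec) -> list[TimedDensitySeries]:
    """Batch growth curves, one per medium dilution.

    Each curve integrates the closed-vessel (D = 0) dynamics from the
    inoculum with initial substrate equal to the dilution, sampled at the
    spec's interval, then perturbed by multiplicative lognormal noise.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.batch_duration_h + 1e-9, spec.sampling_interval_h)
    out = []
    for dilution in spec.dilutions:
        config = ChemostatConfig(Sr=0.0, D=0.0, params=spec.params)
        traj = simulate(
            config, X0=spec.inoculum, S0=dilution,
            t_end=spec.batch_duration_h, n_samples=times.size,
        )
        values = traj.X * _lognormal_factors(rng, spec.noise_cv, times.size)
        out.append(TimedDensitySeries(times=traj.t, values=values, dilution=dilution))
    return out


def gen_biofilm_counts(
    spec: SyntheticSpec,
    D_list: Sequence[float],
    true_mu_by_D: Mapping[float, float],
    X0_true: float,
) -> list[BiofilmObservation]:
    """Biofilm assay summaries with known growth rates.

    For each dilution rate the final density X0_true * exp(mu * exposure) is
    observed through ``n_stacks`` lognormal per-stack counts; the summary
    reports their mean, sample SD (0 for a single stack) and count.
    """
    if X0_true <= 0:
        raise ValueError("X0_true must be positive")
    rng = np.random.default_rng(spec.seed)
    n_stacks = list(spec.n_stacks)
    if len(n_stacks) < len(D_list):
        raise ValueError("spec.n_stacks must provide a count per dilution rate")
    out = []
    for D, n in zip(D_list, n_stacks):
        mu = float(true_mu_by_D[D])
        final = X0_true * np.exp(mu * spec.exposure_h)
        draws = final * _lognormal_factors(rng, spec.stack_cv, n)
        sd = float(np.std(draws, ddof=1)) if n > 1 else 0.0
        out.append(
            BiofilmObservation(
                D=D, exposure_h=spec.exposure_h, mean_density=float(np.mean(draws)),
                sd_density=sd, n_stacks=n,
            )
        )
    return out


def gen_chemostat_series(
    spec: SyntheticSpec,
    config: ChemostatConfig,
    observation_noise_cv: float = 0.0,
    X0: float = 1e-3,
    S0: float | None = None,
    t_end: float | None = None,
    n_samples: int = 101,
) -> Trajectory:
    """Noisy sampled chemostat trajectory (simulate, then perturb X and S)."""
    if S0 is None:
        S0 = config.Sr
    if t_end is None:
        t_end = 50.0 / config.D if config.D > 0 else 24.0
    rng = np.random.default_rng(spec.seed)
    traj = simulate(config, X0=X0, S0=S0, t_end=t_end, n_samples=n_samples)
    X = traj.X * _lognormal_factors(rng, observation_noise_cv, n_samples)
    S = traj.S * _lognormal_factors(rng, observation_noise_cv, n_samples)
    return replace(traj, X=X, S=S)
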