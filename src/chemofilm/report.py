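"""Report tables for the packaged reference scenario.

Regenerates, from the bundled constants alone, the steady-state substrate
table at the three bench dilution rates and the combined biofilm assay
summary, in full precision plus a companion rounded to the precision the
bench tables print (2 significant figures for substrate concentrations).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .biofilm import summarize_assays
from .chemostat import ChemostatConfig, steady_state_substrate, sweep
from .datasets import (
    CASE2_SR,
    EXPERIMENT_DILUTION_RATES,
    REFERENCE_PARAMS,
    reference_biofilm_observations,
)
from .io import round_sig
from .monod import MonodParameters

__all__ = ["steady_substrate_table", "assay_summary_table", "plot_sweep"]


def steady_substrate_table(
    D_values: Sequence[float] = EXPERIMENT_DILUTION_RATES,
    params: MonodParameters = REFERENCE_PARAMS,
    sig_figs: int | None = 2,
) -> pd.DataFrame:
    """Steady-state substrate and its multiple of Ks per dilution rate.

    ``sig_figs`` adds rounded companion columns (``None`` for full precision
    only).
    """
    S = np.array([steady_state_substrate(D, params) for D in D_values])
    df = pd.DataFrame({"D": list(D_values), "S_bar": S, "S_bar_over_Ks": S / params.Ks})
    if sig_figs is not None:
        df["S_bar_rounded"] = [round_sig(v, sig_figs) for v in df["S_bar"]]
        df["S_bar_over_Ks_rounded"] = [round_sig(v, sig_figs) for v in df["S_bar_over_Ks"]]
    return df


def assay_summary_table(
    observations=None,
    reference_D: float | None = None,
    params: MonodParameters = REFERENCE_PARAMS,
    Sr: float = CASE2_SR,
) -> pd.DataFrame:
    """Biofilm assay summary for the bundled measurements (or supplied ones)."""
    if observations is None:
        observations = reference_biofilm_observations()
    return summarize_assays(observations, reference_D=reference_D, params=params, Sr=Sr)


def plot_sweep(base: ChemostatConfig, D_grid, path) -> None:
    """Best-effort line plot of S_bar, X_bar and P over a dilution-rate sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep(base, D_grid).to_dataframe()
    fig, ax_P = plt.subplots(figsize=(6, 4))
    ax_SX = ax_P.twinx()
    ax_P.plot(df["D"], df["P"], color="tab:red", label="P")
    ax_SX.plot(df["D"], df["X_bar"], color="tab:blue", label="X")
    ax_SX.plot(df["D"], df["S_bar"], color="tab:green", label="S")
    ax_P.set_xlabel("dilution rate D (h$^{-1}$)")
    ax_P.set_ylabel("production P (a.u. h$^{-1}$)", color="tab:red")
    ax_SX.set_ylabel("X, S (a.u.)")
    ax_SX.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
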