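"""CSV/JSON/YAML readers and writers.

All CSV files are comma-separated UTF-8 with a mandatory header row and
``.`` decimals; scientific notation is accepted on read and emitted for
magnitudes outside [1e-3, 1e6).  Writers prepend ``#``-prefixed metadata
lines (constants, seed, package version) sufficient to re-run the producing
command; readers skip them, and floats round-trip at full precision
(``repr`` formatting).
"""

from __future__ import annotations

import io as _stdio
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biofilm import BiofilmObservation
from .chemostat import ChemostatConfig, DilutionSweep
from .datasets import reference_config
from .monod import MonodParameters, TimedDensitySeries

__all__ = [
    "round_sig",
    "format_number",
    "read_growth_csv",
    "write_growth_csv",
    "read_biofilm_csv",
    "write_biofilm_csv",
    "write_sweep_csv",
    "read_config",
    "write_dataframe_csv",
    "read_dataframe_csv",
]

GROWTH_COLUMNS = ["series_id", "dilution", "time_h", "value"]
BIOFILM_COLUMNS = [
    "D_per_h",
    "exposure_h",
    "mean_cells_per_cm2",
    "sd_cells_per_cm2",
    "n_stacks",
    "nonviable_fraction",
]


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures, ties away from zero.

    This is the convention of the printed report tables (e.g. 0.0017449 ->
    0.0017 at 2 s.f.); internal computation is always full precision.
    """
    if n < 1:
        raise ValueError("need at least one significant figure")
    if x == 0 or not np.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    shift = n - d.adjusted() - 1
    return float(d.scaleb(shift).to_integral_value(rounding=ROUND_HALF_UP).scaleb(-shift))


def format_number(x: float) -> str:
    """Full-precision decimal text, scientific for |x| outside [1e-3, 1e6)."""
    if x == 0:
        return "0"
    if 1e-3 <= abs(x) < 1e6:
        return repr(float(x))
    return f"{x:.17e}"


def _metadata_lines(meta: Mapping | None) -> str:
    lines = [f"# chemofilm {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + "\n"


def write_dataframe_csv(df: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    """Write a DataFrame with a ``#`` metadata header, full float precision."""
    buf = _stdio.StringIO()
    df.to_csv(buf, index=False, float_format=None)
    Path(path).write_text(_metadata_lines(meta) + buf.getvalue(), encoding="utf-8")


def read_dataframe_csv(path, required_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV, skipping metadata comments and validating the header."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty CSV (no header row)") from None
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_growth_csv(series: Sequence[TimedDensitySeries], path, meta=None) -> None:
    rows = []
    for i, s in enumerate(series):
        label = s.dilution if s.dilution is not None else ""
        for t, v in zip(s.times, s.values):
            rows.append((f"series_{i}", label, float(t), float(v)))
    df = pd.DataFrame(rows, columns=GROWTH_COLUMNS)
    write_dataframe_csv(df, path, meta)


def read_growth_csv(path) -> list[TimedDensitySeries]:
    """Parse a growth-curve CSV into one series per ``series_id``."""
    df = read_dataframe_csv(path, GROWTH_COLUMNS)
    if df.empty:
        raise ValueError(f"{path}: no growth-curve rows")
    out = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("time_h")
        dilution = grp["dilution"].iloc[0]
        dilution = None if pd.isna(dilution) else float(dilution)
        out.append(
            TimedDensitySeries(
                times=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                dilution=dilution,
            )
        )
    return out


def write_biofilm_csv(observations: Sequence[BiofilmObservation], path, meta=None) -> None:
    df = pd.DataFrame(
        [
            (
                o.D,
                o.exposure_h,
                o.mean_density,
                o.sd_density if o.sd_density is not None else np.nan,
                o.n_stacks,
                o.nonviable_fraction,
            )
            for o in observations
        ],
        columns=BIOFILM_COLUMNS,
    )
    write_dataframe_csv(df, path, meta)


def read_biofilm_csv(path) -> list[BiofilmObservation]:
    df = read_dataframe_csv(path, BIOFILM_COLUMNS)
    out = []
    for _, row in df.iterrows():
        sd = row["sd_cells_per_cm2"]
        out.append(
            BiofilmObservation(
                D=float(row["D_per_h"]),
                exposure_h=float(row["exposure_h"]),
                mean_density=float(row["mean_cells_per_cm2"]),
                sd_density=None if pd.isna(sd) else float(sd),
                n_stacks=int(row["n_stacks"]),
                nonviable_fraction=float(row["nonviable_fraction"]),
            )
        )
    return out


def write_sweep_csv(sweep_result: DilutionSweep, path, meta=None) -> None:
    base = sweep_result.base
    full_meta = {
        "mu_max": base.params.mu_max,
        "Ks": base.params.Ks,
        "Y": base.params.Y,
        "Sr": base.Sr,
        **(meta or {}),
    }
    write_dataframe_csv(sweep_result.to_dataframe(), path, full_meta)


def read_config(path) -> list[ChemostatConfig]:
    """Load chemostat config(s) from YAML or JSON.

    Keys: ``mu_max``, ``Ks``, ``Y``, ``Sr``, ``D`` (scalar or list), or a
    ``case`` preset (``case1``/``case2``) whose constants individual keys may
    override.  Returns one config per dilution rate.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "case" in data:
        preset = reference_config(str(data["case"]))
        defaults = {
            "mu_max": preset.params.mu_max,
            "Ks": preset.params.Ks,
            "Y": preset.params.Y,
            "Sr": preset.Sr,
        }
    else:
        defaults = {}
    merged = {**defaults, **{k: v for k, v in data.items() if k != "case"}}
    try:
        params = MonodParameters(
            mu_max=float(merged["mu_max"]),
            Ks=float(merged["Ks"]),
            Y=float(merged.get("Y", 0.4)),
        )
        Sr = float(merged["Sr"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing config key {exc}") from None
    D_raw = merged.get("D", 0.0)
    D_values = [float(d) for d in (D_raw if isinstance(D_raw, (list, tuple)) else [D_raw])]
    return [ChemostatConfig(Sr=Sr, D=d, params=params) for d in D_values]
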