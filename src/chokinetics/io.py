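"""Readers and writers for culture time-series tables.

File schema: comma-delimited text with a mandatory header.  Columns
``time_h, viable_cells_per_ml, glucose_g_per_l, lactate_g_per_l,
mab_mg_per_l, condition, replicate`` are required; ``volume_ml`` and
``temperature_c`` are optional.  Missing measurements are empty cells.
Units in file names match the package's canonical units exactly, so no
numeric conversion happens here — only validation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import CultureTimeSeries

__all__ = ["read_timeseries", "write_timeseries", "MANDATORY_COLUMNS"]

MANDATORY_COLUMNS = (
    "time_h",
    "viable_cells_per_ml",
    "glucose_g_per_l",
    "lactate_g_per_l",
    "mab_mg_per_l",
    "condition",
    "replicate",
)
OPTIONAL_COLUMNS = ("volume_ml", "temperature_c")

_COLUMN_TO_FIELD = {
    "viable_cells_per_ml": "X",
    "glucose_g_per_l": "S",
    "lactate_g_per_l": "Lac",
    "mab_mg_per_l": "P",
    "volume_ml": "volume",
    "temperature_c": "temperature",
}


class SchemaError(ValueError):
    """The table violates the time-series schema."""


def read_timeseries(path: str | Path) -> list[CultureTimeSeries]:
    """Read a CSV of culture samples into one series per (condition, replicate).

    Rows must already be in time order within each series — out-of-order or
    duplicate times are errors, never silently repaired.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    out: list[CultureTimeSeries] = []
    for (condition, replicate), grp in df.groupby(
        ["condition", "replicate"], sort=True
    ):
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise SchemaError(
                f"{path.name}: duplicate time for (condition={condition!r}, "
                f"replicate={replicate!r})"
            )
        if np.any(np.diff(t) < 0):
            raise SchemaError(
                f"{path.name}: time not increasing for (condition={condition!r}, "
                f"replicate={replicate!r}); refusing to sort silently"
            )
        kwargs = {}
        for col, fld in _COLUMN_TO_FIELD.items():
            if col in grp.columns:
                vals = grp[col].to_numpy(dtype=float)
                kwargs[fld] = None if np.all(np.isnan(vals)) else vals
        out.append(
            CultureTimeSeries(
                time=t,
                condition=str(condition),
                replicate=str(replicate),
                **kwargs,
            )
        )
    return out


def write_timeseries(series_list: list[CultureTimeSeries], path: str | Path) -> None:
    """Write series to the canonical CSV schema (empty cells for missing)."""
    rows = []
    for s in series_list:
        for i in range(s.n_samples):
            def val(arr):
                if arr is None or not np.isfinite(arr[i]):
                    return None
                return arr[i]

            rows.append(
                {
                    "time_h": s.time[i],
                    "viable_cells_per_ml": val(s.X),
                    "glucose_g_per_l": val(s.S),
                    "lactate_g_per_l": val(s.Lac),
                    "mab_mg_per_l": val(s.P),
                    "volume_ml": val(s.volume),
                    "temperature_c": val(s.temperature),
                    "condition": s.condition,
                    "replicate": s.replicate,
                }
            )
    df = pd.DataFrame(rows)
    if df["volume_ml"].isna().all() and df["temperature_c"].isna().all():
        df = df.drop(columns=["volume_ml", "temperature_c"])
    df.to_csv(path, index=False)
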