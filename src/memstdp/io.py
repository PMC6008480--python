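"""Result persistence: rasters, protocol tables, metrics, config echoes.

CSV dialect: comma-separated, header row, '.' decimal.  Weight matrices
are exchanged as plain-text dense matrices (row = source neuron).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "save_raster_csv",
    "load_raster_csv",
    "save_protocol_csv",
    "save_completion_csv",
    "save_json",
    "save_config_json",
]


def save_raster_csv(result, path) -> None:
    pd.DataFrame(
        {"neuron_id": result.spike_neurons, "time_ms": result.spike_times_ms}
    ).to_csv(path, index=False)


def load_raster_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["neuron_id"].to_numpy(), df["time_ms"].to_numpy()


def save_protocol_csv(result, path, var_name: str) -> None:
    """Tidy table: independent variable, weight change, branch, leak mode."""
    meta = result.meta
    pd.DataFrame(
        {
            var_name: result.grid,
            "weight_change_percent": result.change_percent,
            "branch": meta.get("branch", meta.get("protocol", "")),
            "leak_mode": "on" if meta.get("leak_between") else "off",
        }
    ).to_csv(path, index=False)


def save_completion_csv(curve, path) -> None:
    pd.DataFrame(
        {
            "e": curve.e_grid,
            "e_fraction": curve.e_fraction,
            "Q": curve.Q,
            "completed_fraction": curve.completed_fraction,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonable) + "\n")


def save_config_json(config: dict, path) -> None:
    save_json(config, path)
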