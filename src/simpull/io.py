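"""Readers and writers for the plain-text interchange formats.

Step-count tables are TSV with columns
``spot_id, condition, replicate, fluorophore, n_steps, intensity``
(an optional boolean ``excluded`` column marks spots removed upstream, e.g.
for 7x7-pixel overlap). Spot tables are CSV with columns
``spot_id, x_px, y_px, intensity, channel``; coordinates are 0-based pixel
centers. Fit results and run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import MixtureFit

__all__ = [
    "read_step_table", "write_step_table",
    "read_spot_table", "write_spot_table",
    "read_bead_pairs", "write_bead_pairs",
    "write_fit", "read_fit", "write_json",
]

STEP_COLUMNS = ["spot_id", "condition", "replicate", "fluorophore",
                "n_steps", "intensity"]
SPOT_COLUMNS = ["spot_id", "x_px", "y_px", "intensity", "channel"]


def read_step_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"step table {path} is missing columns {missing}")
    return df


def write_step_table(df: pd.DataFrame, path) -> None:
    cols = STEP_COLUMNS + (["excluded"] if "excluded" in df.columns else [])
    df[cols].to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} is missing columns {missing}")
    return df


def write_spot_table(df: pd.DataFrame, path) -> None:
    df[SPOT_COLUMNS].to_csv(path, index=False)


def read_bead_pairs(path) -> np.ndarray:
    """Bead pair CSV with columns x_src, y_src, x_dst, y_dst."""
    df = pd.read_csv(path)
    need = ["x_src", "y_src", "x_dst", "y_dst"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"bead table {path} is missing columns {missing}")
    return df[need].to_numpy(float)


def write_bead_pairs(arr, path) -> None:
    pd.DataFrame(np.asarray(arr, float),
                 columns=["x_src", "y_src", "x_dst", "y_dst"]
                 ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_fit(fit: MixtureFit, path) -> None:
    write_json(fit.to_dict(), path)


def read_fit(path) -> MixtureFit:
    with open(path) as fh:
        return MixtureFit(**json.load(fh))
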