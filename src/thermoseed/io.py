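"""CSV readers/writers for curves, labels and feature tables.

All tabular artifacts are plain CSV so a run's outputs round-trip
through pandas without loss of structure.  Floats are written with
repr-level precision; rerunning a configured experiment with the same
seed reproduces each file byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import TemperatureCurve

__all__ = [
    "write_curves_csv",
    "read_curves_csv",
    "write_labels_csv",
    "read_labels_csv",
]


def write_curves_csv(curves: list[TemperatureCurve], path) -> None:
    """Long-format per-seed curves: seed_id, time_min, rT_c."""
    frames = []
    for curve in curves:
        frames.append(pd.DataFrame({
            "seed_id": curve.seed_id,
            "time_min": curve.times_min,
            "rT_c": curve.r_t,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> list[TemperatureCurve]:
    df = pd.read_csv(path)
    required = {"seed_id", "time_min", "rT_c"}
    if not required <= set(df.columns):
        raise ValueError(f"curve CSV needs columns {sorted(required)}")
    curves = []
    for sid, sub in df.groupby("seed_id", sort=True):
        sub = sub.sort_values("time_min")
        curves.append(TemperatureCurve(
            seed_id=sid,
            times_min=sub["time_min"].to_numpy(float),
            r_t=sub["rT_c"].to_numpy(float),
        ))
    return curves


def write_labels_csv(seed_ids, root_lengths_cm, classes, path) -> None:
    pd.DataFrame({
        "seed_id": np.asarray(seed_ids),
        "root_length_cm": np.asarray(root_lengths_cm, dtype=float),
        "class": np.asarray(classes),
    }).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "seed_id" not in df.columns:
        raise ValueError("label CSV needs a seed_id column")
    return df.set_index("seed_id")


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
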