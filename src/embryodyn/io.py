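"""Readers and writers shared by all pipeline stages.

Tabular artefacts are plain CSV with fixed schemas; reports are JSON with
sorted keys so reruns with the same seed are byte-identical; images are
(multi-page) TIFF via tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    NUCLEAR_COLUMNS,
    TRAJECTORY_COLUMNS,
    DecaySeries,
    NuclearArray,
    TrajectorySet,
)

_FLOAT_FORMAT = "%.9g"


def write_trajectories(trajectories: TrajectorySet, path: str | Path) -> None:
    df = trajectories.data[TRAJECTORY_COLUMNS]
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trajectories(
    path: str | Path, dt: float | None = None, pixel_size: float | None = None
) -> TrajectorySet:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.astype({"frame": int, "t_s": float, "x_um": float, "y_um": float})
    dup = df.duplicated(subset=["particle_id", "frame"])
    if dup.any():
        # +2: one for the header line, one for 1-based numbering
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate (particle_id, frame) at line {line}")
    bad = ~np.isfinite(df[["x_um", "y_um", "t_s"]].to_numpy(float)).all(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-finite value at line {line}")
    if dt is None:
        steps = (
            df.sort_values(["particle_id", "frame"])
            .groupby("particle_id")["t_s"]
            .diff()
            .dropna()
        )
        dt = float(steps.min()) if len(steps) else 1.0
    return TrajectorySet(data=df, dt=dt, pixel_size=pixel_size)


def write_nuclear_array(array: NuclearArray, path: str | Path) -> None:
    array.data[NUCLEAR_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_nuclear_array(path: str | Path, bbox=None) -> NuclearArray:
    df = pd.read_csv(path)
    missing = [c for c in NUCLEAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df["nucleus_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate nucleus_id at line {line}")
    return NuclearArray(data=df, bbox=bbox)


def write_decay_series(series: DecaySeries, path: str | Path) -> None:
    pd.DataFrame({"t_s": series.t, "intensity_norm": series.intensity}).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def read_decay_series(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path)
    for col in ("t_s", "intensity_norm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return DecaySeries(
        t=df["t_s"].to_numpy(float), intensity=df["intensity_norm"].to_numpy(float)
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a (frames, rows, cols) stack."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr
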