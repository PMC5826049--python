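"""In-memory containers shared by the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["particle_id", "frame", "t_s", "x_um", "y_um"]
NUCLEAR_COLUMNS = ["nucleus_id", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """Per-particle time series of 2-D positions in micrometres.

    ``data`` holds one row per (particle, frame) with columns
    ``particle_id, frame, t_s, x_um, y_um`` on the uniform grid
    t_j = frame * dt. Frames may be missing inside a trajectory (a linking
    gap); downstream analyses decide how to treat gapped tracks.
    """

    data: pd.DataFrame
    dt: float
    pixel_size: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError(f"dt must be a positive finite number, got {self.dt}")
        if len(self.data):
            dup = self.data.duplicated(subset=["particle_id", "frame"])
            if dup.any():
                row = int(np.flatnonzero(dup.to_numpy())[0])
                raise ValueError(f"duplicate (particle_id, frame) at row {row}")
            xy = self.data[["x_um", "y_um"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                raise ValueError("non-finite positions in trajectory table")

    @property
    def particle_ids(self) -> list:
        return sorted(self.data["particle_id"].unique().tolist())

    @property
    def n_particles(self) -> int:
        return self.data["particle_id"].nunique()

    def positions(self, particle_id) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (frames, t, xy) for one particle, sorted by frame."""
        sub = self.data[self.data["particle_id"] == particle_id].sort_values("frame")
        if sub.empty:
            raise KeyError(f"unknown particle id {particle_id!r}")
        frames = sub["frame"].to_numpy(int)
        t = sub["t_s"].to_numpy(float)
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        return frames, t, xy

    def __len__(self) -> int:
        return self.n_particles


@dataclass
class NuclearArray:
    """Segmented nuclear centroids (µm) with the field-of-view bounding box."""

    data: pd.DataFrame
    bbox: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in NUCLEAR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"nuclear table missing columns {missing}")
        if self.data["nucleus_id"].duplicated().any():
            raise ValueError("nucleus ids must be unique")
        if self.bbox is None and len(self.data):
            x = self.data["x_um"].to_numpy(float)
            y = self.data["y_um"].to_numpy(float)
            self.bbox = (float(x.min()), float(x.max()), float(y.min()), float(y.max()))

    @property
    def points(self) -> np.ndarray:
        return self.data[["x_um", "y_um"]].to_numpy(float)

    @property
    def ids(self) -> np.ndarray:
        return self.data["nucleus_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DecaySeries:
    """Background-subtracted total-fluorescence time course.

    ``t`` is seconds since injection; ``intensity`` is normalized so the
    pre-injection reference ``i0`` maps to 1.
    """

    t: np.ndarray
    intensity: np.ndarray
    i0: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have the same shape")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("time points must be non-decreasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities in decay series")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class BoxStats:
    """Five-number summary used for box plots: quartile box, min/max whiskers."""

    q1: float
    median: float
    q3: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("box statistics must be ordered min<=q1<=median<=q3<=max")
        if self.n < 1:
            raise ValueError("n must be >= 1")
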