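"""Shared configuration types for simulation and analysis.

All geometry is handled in micrometres internally; pixel units appear only
at the image rendering / ingestion boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition geometry and time grid of a synthetic recording.

    Parameters
    ----------
    seed
        Root seed for every stream of randomness derived from this config.
    dt
        Seconds per frame. Centrosome recordings are acquired at 1 Hz,
        hence the default of 1 s.
    duration
        Total recorded time in seconds (default 220 s, the span over which
        centrosome trajectories are followed).
    pixel_size
        Micrometres per pixel at the camera.
    image_shape
        Frame shape in pixels as (rows, cols).
    """

    seed: int = 0
    dt: float = 1.0
    duration: float = 220.0
    pixel_size: float = 0.2
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        for name in ("dt", "duration", "pixel_size"):
            _require_finite(name, getattr(self, name))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.duration < 2 * self.dt:
            raise ValueError(
                f"duration must cover at least two frames (>= {2 * self.dt}), "
                f"got {self.duration}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")

    @property
    def n_frames(self) -> int:
        """Number of samples on the uniform grid t_j = j*dt, j = 0..duration/dt."""
        return int(round(self.duration / self.dt)) + 1

    def times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth parameters of the synthetic embryo.

    ``true_D`` is the apparent diffusion constant of centrosome fluctuations
    (µm²/s); ``relaxation_time`` the tether relaxation time of the
    crosslinked (wild-type-like) regime, giving an Ornstein-Uhlenbeck
    stationary variance of ``true_D * relaxation_time`` per axis.
    ``lattice_spacing`` is the internuclear distance of the cortical nuclear
    array; ``positional_noise_sd`` and ``defect_rate`` control its disorder.
    ``true_half_life`` parameterises the fluorescence-depletion movie.
    """

    true_D: float = 0.01
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    relaxation_time: float = 20.0
    lattice_spacing: float = 5.0
    positional_noise_sd: float = 0.25
    defect_rate: float = 0.0
    true_half_life: float = 1800.0

    def __post_init__(self) -> None:
        _require_finite("true_D", self.true_D)
        _require_finite("relaxation_time", self.relaxation_time)
        _require_finite("lattice_spacing", self.lattice_spacing)
        _require_finite("positional_noise_sd", self.positional_noise_sd)
        _require_finite("defect_rate", self.defect_rate)
        _require_finite("true_half_life", self.true_half_life)
        for v in self.drift_velocity:
            _require_finite("drift_velocity", v)
        if self.true_D < 0:
            raise ValueError(f"true_D must be >= 0, got {self.true_D}")
        if self.relaxation_time <= 0:
            raise ValueError(
                f"relaxation_time must be > 0, got {self.relaxation_time}"
            )
        if not (0 <= self.defect_rate < 1):
            raise ValueError(f"defect_rate must be in [0, 1), got {self.defect_rate}")
        if self.lattice_spacing <= 0:
            raise ValueError(
                f"lattice_spacing must be > 0, got {self.lattice_spacing}"
            )
        if self.positional_noise_sd < 0:
            raise ValueError(
                f"positional_noise_sd must be >= 0, got {self.positional_noise_sd}"
            )
        if self.true_half_life <= 0:
            raise ValueError(
                f"true_half_life must be > 0, got {self.true_half_life}"
            )
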