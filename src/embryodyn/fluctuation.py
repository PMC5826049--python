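"""Drift-subtracted centrosome fluctuation analysis.

Centrosome motion in the syncytial cortex superposes slow, minute-scale
drift (collective flows, stage drift) on fast second-scale fluctuations.
The fluctuation parameter D_i isolates the fast component: the drift is
estimated as a centred moving average of the trajectory, and the residual
per-step squared displacement, divided by 4*lag*dt (the 2-D convention),
is averaged over time. D_i has the dimension of a diffusion constant and
can be read as the apparent diffusion of centrosome i about its drift.

Per-particle time averaging comes first, then ensemble statistics over
particles, so each centrosome contributes one D_i regardless of track
length. Conditions are compared by the fold change of mean D and a
two-sided pooled-variance Student's t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BoxStats, TrajectorySet

logger = logging.getLogger(__name__)

DEFAULT_DRIFT_WINDOW_S = 60.0  # "minute-scale" drift
DEFAULT_LAG_FRAMES = 1  # finest available scale at 1 Hz


@dataclass
class DriftTrack:
    """Moving-average drift estimate on the trajectory's own time grid.

    ``interior`` flags samples whose averaging window was not truncated at
    the trajectory ends; only these enter the fluctuation average.
    """

    smoothed: np.ndarray  # (n, 2) µm
    window_s: float
    window_samples: int
    interior: np.ndarray  # (n,) bool


@dataclass
class FluctuationResult:
    particle_ids: list
    D: np.ndarray  # µm²/s, one per retained particle
    n_steps: np.ndarray  # valid steps per particle
    box: BoxStats
    excluded: list = field(default_factory=list)  # (particle_id, reason)
    drift_window_s: float | None = None
    lag_frames: int = DEFAULT_LAG_FRAMES

    @property
    def mean_D(self) -> float:
        return float(np.mean(self.D))


@dataclass(frozen=True)
class ConditionComparison:
    fold_change: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average with symmetric truncation at the ends.

    At index j the half-width shrinks to min(h, j, n-1-j), so the window
    stays centred on j; ``window_samples`` must be odd.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError(f"window_samples must be odd and >= 1, got {window_samples}")
    x = np.asarray(x, float)
    n = x.shape[0]
    h = window_samples // 2
    # cumulative sum along time for O(n) windowed means
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    out = np.empty_like(x)
    for j in range(n):
        hj = min(h, j, n - 1 - j)
        out[j] = (c[j + hj + 1] - c[j - hj]) / (2 * hj + 1)
    return out


def window_samples_from_seconds(window_s: float, dt: float) -> int:
    """Convert a window in seconds to an odd sample count (round(w/dt)+1)."""
    w = int(round(window_s / dt)) + 1
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def estimate_drift(xy: np.ndarray, dt: float, window_s: float = DEFAULT_DRIFT_WINDOW_S) -> DriftTrack:
    """Estimate the slow drift of one trajectory by centred moving average."""
    xy = np.asarray(xy, float)
    w = window_samples_from_seconds(window_s, dt)
    n = len(xy)
    if n < w:
        raise ValueError(
            f"trajectory of {n} samples is shorter than the drift window "
            f"({w} samples)"
        )
    h = w // 2
    interior = np.zeros(n, bool)
    interior[h : n - h] = True
    return DriftTrack(
        smoothed=moving_average(xy, w), window_s=window_s, window_samples=w,
        interior=interior,
    )


def fluctuation_parameter(
    xy: np.ndarray,
    dt: float,
    drift: DriftTrack | None = None,
    lag: int = DEFAULT_LAG_FRAMES,
) -> tuple[float, int]:
    """Time-averaged fluctuation parameter D_i of one trajectory.

    Residuals r(t_j) = position - drift; per-step fluctuation
    |r(t_{j+lag}) - r(t_j)|^2 / (4 * lag * dt); D_i is the mean over steps
    whose endpoints both have untruncated drift windows. With
    ``drift=None`` no drift is subtracted and all steps are used (then
    E[D_i] equals the true diffusion constant for free Brownian input).

    Returns (D_i, number of steps used).
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1 frame, got {lag}")
    xy = np.asarray(xy, float)
    n = len(xy)
    if drift is None:
        resid = xy
        valid = np.ones(n, bool)
    else:
        if drift.smoothed.shape != xy.shape:
            raise ValueError("drift track must be on the same grid as the trajectory")
        resid = xy - drift.smoothed
        valid = drift.interior
    use = valid[: n - lag] & valid[lag:]
    n_steps = int(use.sum())
    if n_steps < 2:
        raise ValueError("fewer than 2 valid interior steps")
    dr = resid[lag:] - resid[: n - lag]
    sq = np.sum(dr * dr, axis=1)[use]
    return float(np.mean(sq) / (4.0 * lag * dt)), n_steps


def analyze_trajectories(
    trajectories: TrajectorySet,
    drift_window_s: float | None = DEFAULT_DRIFT_WINDOW_S,
    lag: int = DEFAULT_LAG_FRAMES,
) -> FluctuationResult:
    """Per-particle D_i for a whole trajectory set, with exclusions logged.

    Particles whose tracks are shorter than the drift window, contain
    frame gaps, or yield fewer than two valid interior steps are excluded
    with a recorded reason rather than failing the run.
    ``drift_window_s=None`` disables drift subtraction.
    """
    dt = trajectories.dt
    ids, Ds, steps, excluded = [], [], [], []
    for pid in trajectories.particle_ids:
        frames, _, xy = trajectories.positions(pid)
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            excluded.append((pid, "frame gap in track"))
            continue
        try:
            drift = (
                None
                if drift_window_s is None
                else estimate_drift(xy, dt, drift_window_s)
            )
            D_i, n_steps = fluctuation_parameter(xy, dt, drift, lag)
        except ValueError as exc:
            excluded.append((pid, str(exc)))
            continue
        ids.append(pid)
        Ds.append(D_i)
        steps.append(n_steps)
    for pid, reason in excluded:
        logger.info("particle %r excluded from fluctuation analysis: %s", pid, reason)
    if not ids:
        raise ValueError("no particle passed the fluctuation-analysis filters")
    D = np.asarray(Ds)
    return FluctuationResult(
        particle_ids=ids,
        D=D,
        n_steps=np.asarray(steps, int),
        box=ensemble_stats(D),
        excluded=excluded,
        drift_window_s=drift_window_s,
        lag_frames=lag,
    )


def ensemble_stats(values: np.ndarray) -> BoxStats:
    """Box-plot summary: quartiles by linear interpolation, min/max whiskers."""
    values = np.asarray(values, float)
    if values.size < 1:
        raise ValueError("ensemble_stats requires at least one value")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        min=float(values.min()),
        max=float(values.max()),
        n=int(values.size),
    )


def compare_conditions(a: np.ndarray, b: np.ndarray) -> ConditionComparison:
    """Fold change of mean D (b over a) and pooled-variance Student's t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs at least 2 values")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_a == 0:
        raise ValueError("fold change undefined: mean of reference condition is 0")
    if np.var(a) == 0 and np.var(b) == 0 and mean_a == mean_b:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return ConditionComparison(
        fold_change=mean_b / mean_a,
        t_statistic=float(t_stat),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
        mean_a=mean_a,
        mean_b=mean_b,
    )
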