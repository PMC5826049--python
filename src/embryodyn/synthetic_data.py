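"""Seeded synthetic embryo recordings with known ground truth.

The generator emulates the statistical structure of the live recordings the
pipeline is built for: (a) 2-D centrosome trajectories made of slow drift
plus fast fluctuations with a known apparent diffusion constant, in a free
(depleted) and a tethered (crosslinked, wild-type-like) regime; (b) the
near-hexagonal cortical nuclear array with tunable positional disorder and
packing defects; (c) monoexponential fluorescence-depletion time courses;
(d) striped expression patterns along a body axis. Each output is a pure
function of (config, truth, call parameters), so identical seeds give
bit-identical results.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GroundTruth, SimulationConfig
from .containers import DecaySeries, NuclearArray, TrajectorySet

# Stream keys keep the randomness of distinct generator products independent:
# adding particles or calling another generator never reshuffles existing draws.
_STREAM_TRAJECTORY = 0
_STREAM_LATTICE = 1
_STREAM_RENDER = 2
_STREAM_DECAY = 3
_STREAM_STRIPES = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _default_initial_positions(n_particles: int, spacing: float) -> np.ndarray:
    """Centred square grid; keeps simulated particles well separated."""
    side = int(math.ceil(math.sqrt(n_particles)))
    idx = np.arange(n_particles)
    rows, cols = divmod(idx, side)
    xy = np.stack([cols, rows], axis=1).astype(float) * spacing
    return xy - xy.mean(axis=0)


def simulate_trajectories(
    config: SimulationConfig,
    truth: GroundTruth,
    n_particles: int,
    tethered: bool = False,
    initial_positions: np.ndarray | None = None,
    label: str = "",
) -> TrajectorySet:
    """Simulate centrosome trajectories on the uniform grid t_j = j*dt.

    Free regime: Brownian motion with diffusion ``truth.true_D`` (µm²/s per
    the 2-D convention MSD = 4*D*t) plus constant drift
    ``truth.drift_velocity`` (µm/s):

        x(t+dt) = x(t) + v*dt + sqrt(2*D*dt)*xi,   xi ~ N(0,1) per axis.

    Tethered regime: Ornstein-Uhlenbeck relaxation toward the particle's
    anchor with time constant tau = ``truth.relaxation_time`` and stationary
    variance D*tau per axis, discretised exactly (no Euler step-size bias):

        x(t+dt) = a + (x-a)*exp(-dt/tau) + sqrt(D*tau*(1-exp(-2dt/tau)))*xi.

    Tethered particles start from a stationary draw so the positional
    variance is saturated from t = 0.
    """
    if n_particles < 1:
        raise ValueError(f"n_particles must be >= 1, got {n_particles}")
    n_frames = config.n_frames
    t = config.times()
    if initial_positions is None:
        initial_positions = _default_initial_positions(
            n_particles, truth.lattice_spacing
        )
    initial_positions = np.asarray(initial_positions, float)
    if initial_positions.shape != (n_particles, 2):
        raise ValueError(
            f"initial_positions must have shape ({n_particles}, 2), "
            f"got {initial_positions.shape}"
        )

    dt = config.dt
    D = truth.true_D
    v = np.asarray(truth.drift_velocity, float)
    tau = truth.relaxation_time

    records = []
    for i in range(n_particles):
        rng = _rng(config.seed, _STREAM_TRAJECTORY, i)
        anchor = initial_positions[i]
        if tethered:
            decay = math.exp(-dt / tau)
            sd_step = math.sqrt(max(D * tau * (1.0 - decay**2), 0.0))
            sd_stat = math.sqrt(D * tau)
            xy = np.empty((n_frames, 2))
            xy[0] = anchor + sd_stat * rng.standard_normal(2)
            noise = rng.standard_normal((n_frames - 1, 2))
            for j in range(1, n_frames):
                xy[j] = anchor + (xy[j - 1] - anchor) * decay + sd_step * noise[j - 1]
        else:
            steps = v * dt + math.sqrt(2.0 * D * dt) * rng.standard_normal(
                (n_frames - 1, 2)
            )
            xy = np.vstack([anchor, anchor + np.cumsum(steps, axis=0)])
        records.append(
            pd.DataFrame(
                {
                    "particle_id": i,
                    "frame": np.arange(n_frames),
                    "t_s": t,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                }
            )
        )
    data = pd.concat(records, ignore_index=True)
    return TrajectorySet(data=data, dt=dt, pixel_size=config.pixel_size, label=label)


def generate_nuclear_array(
    config: SimulationConfig,
    truth: GroundTruth,
    n_rows: int,
    n_cols: int,
    label: str = "",
) -> NuclearArray:
    """Jittered triangular lattice emulating the cortical nuclear array.

    Sites sit on a hexagonal-packing lattice with spacing
    ``truth.lattice_spacing``, each displaced by isotropic Gaussian noise of
    s.d. ``truth.positional_noise_sd``. Packing defects: with probability
    ``defect_rate/2`` a site is deleted (emulating a missing/fused nucleus)
    and with probability ``defect_rate/2`` it is displaced by half a lattice
    spacing in a random direction (a mispositioned nucleus). Together these
    produce both under- and over-coordinated nuclei.
    """
    if n_rows < 3 or n_cols < 3:
        raise ValueError(
            f"lattice must be at least 3x3 to contain an interior nucleus, "
            f"got {n_rows}x{n_cols}"
        )
    s = truth.lattice_spacing
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    x = (cols + 0.5 * (rows % 2)) * s
    y = rows * (s * math.sqrt(3.0) / 2.0)
    pts = np.stack([x.ravel(), y.ravel()], axis=1)
    bbox = (
        float(pts[:, 0].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].min()),
        float(pts[:, 1].max()),
    )

    rng = _rng(config.seed, _STREAM_LATTICE)
    n = len(pts)
    # Draw all randomness in a fixed order so changing one truth parameter
    # does not reshuffle the remaining draws.
    jitter = rng.standard_normal((n, 2)) * truth.positional_noise_sd
    fate = rng.uniform(size=n)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n)

    pts = pts + jitter
    half = truth.defect_rate / 2.0
    displaced = (fate >= half) & (fate < 2 * half)
    pts[displaced] += 0.5 * s * np.stack(
        [np.cos(angles[displaced]), np.sin(angles[displaced])], axis=1
    )
    keep = fate >= half  # fate < half -> deleted site
    pts = pts[keep]

    data = pd.DataFrame(
        {"nucleus_id": np.arange(len(pts)), "x_um": pts[:, 0], "y_um": pts[:, 1]}
    )
    return NuclearArray(data=data, bbox=bbox, label=label)


def render_image(
    points_um: np.ndarray,
    config: SimulationConfig,
    psf_sigma: float,
    snr: float,
    background: float = 100.0,
    amplitude: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render point emitters as Gaussian spots in a 16-bit frame.

    ``psf_sigma`` is in µm; ``snr`` is peak amplitude over noise s.d.
    (``numpy.inf`` disables noise). Column index is x, row index is y,
    origin at the top-left pixel centre.
    """
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma}")
    if not snr > 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    rows, cols = config.image_shape
    px = config.pixel_size
    points_um = np.asarray(points_um, float).reshape(-1, 2)
    img = np.zeros((rows, cols), float)
    sigma_px = psf_sigma / px
    win = max(1, int(math.ceil(4.0 * sigma_px)))
    for x_um, y_um in points_um:
        cx, cy = x_um / px, y_um / px
        if not (0 <= cx < cols and 0 <= cy < rows):
            raise ValueError(
                f"point ({x_um}, {y_um}) µm falls outside the {rows}x{cols} frame"
            )
        x0, x1 = max(0, int(cx) - win), min(cols, int(cx) + win + 1)
        y0, y1 = max(0, int(cy) - win), min(rows, int(cy) + win + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2)
        img[y0:y1, x0:x1] += amplitude * np.outer(gy, gx)
    img += background
    if np.isfinite(snr):
        if rng is None:
            rng = _rng(config.seed, _STREAM_RENDER)
        img += (amplitude / snr) * rng.standard_normal(img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_trajectory_movie(
    trajectories: TrajectorySet,
    config: SimulationConfig,
    psf_sigma: float,
    snr: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
    background: float = 100.0,
    amplitude: float = 1000.0,
) -> np.ndarray:
    """Render a TrajectorySet as a multi-frame stack (one shared noise stream)."""
    rng = _rng(config.seed, _STREAM_RENDER)
    frames = sorted(trajectories.data["frame"].unique())
    stack = []
    ox, oy = origin_um
    for f in frames:
        sub = trajectories.data[trajectories.data["frame"] == f]
        pts = sub[["x_um", "y_um"]].to_numpy(float) - np.array([ox, oy])
        stack.append(
            render_image(
                pts,
                config,
                psf_sigma=psf_sigma,
                snr=snr,
                background=background,
                amplitude=amplitude,
                rng=rng,
            )
        )
    return np.stack(stack)


def simulate_decay_series(
    config: SimulationConfig,
    truth: GroundTruth,
    plateau_fraction: float = 0.0,
    noise_sd: float = 0.0,
    i0: float = 1.0,
    label: str = "",
) -> DecaySeries:
    """Monoexponential fluorescence depletion toward a plateau.

        I(t) = I_inf + (I_0 - I_inf) * exp(-ln2 * t / true_half_life),

    with I_inf = plateau_fraction * I_0, sampled on the config time grid,
    plus additive Gaussian noise of s.d. ``noise_sd`` (in units of I_0).
    """
    if not (0 <= plateau_fraction < 1):
        raise ValueError(
            f"plateau_fraction must be in [0, 1), got {plateau_fraction}"
        )
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    t = config.times()
    i_inf = plateau_fraction * i0
    intensity = i_inf + (i0 - i_inf) * np.exp(
        -math.log(2.0) * t / truth.true_half_life
    )
    if noise_sd > 0:
        rng = _rng(config.seed, _STREAM_DECAY)
        intensity = intensity + noise_sd * i0 * rng.standard_normal(t.shape)
    return DecaySeries(t=t, intensity=intensity, i0=i0, label=label)


def simulate_decay_movie(
    config: SimulationConfig,
    truth: GroundTruth,
    plateau_fraction: float = 0.0,
    noise_sd: float = 0.0,
    background: float = 100.0,
    peak: float = 1000.0,
) -> tuple[DecaySeries, np.ndarray]:
    """Decay series plus a rendered uniform-field movie following it.

    Each frame is a flat field at ``background + peak * I(t)`` with the
    same per-frame multiplicative series as :func:`simulate_decay_series`;
    pixel noise is applied per frame so total fluorescence fluctuates
    realistically.
    """
    series = simulate_decay_series(
        config, truth, plateau_fraction=plateau_fraction, noise_sd=0.0
    )
    rng = _rng(config.seed, _STREAM_DECAY)
    rows, cols = config.image_shape
    stack = np.empty((len(series), rows, cols), dtype=np.uint16)
    for j, level in enumerate(series.intensity):
        frame = background + peak * level * np.ones((rows, cols))
        if noise_sd > 0:
            frame = frame + noise_sd * peak * rng.standard_normal((rows, cols))
        stack[j] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
    noisy = series.intensity.copy()
    if noise_sd > 0:
        # summary series carries the same noise scale as a single pixel row
        noisy = noisy + noise_sd * _rng(
            config.seed, _STREAM_DECAY, 1
        ).standard_normal(noisy.shape)
    return DecaySeries(t=series.t, intensity=noisy, i0=series.i0), stack


def make_stripe_image(
    config: SimulationConfig,
    stripe_period_um: float,
    stripe_width_um: float,
    depletion: float,
    high: float = 1000.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Striped expression pattern along the x (anterior-posterior) axis.

    Intensity is ``high`` outside stripes and ``depletion * high`` inside
    periodic stripes of width ``stripe_width_um``. Returns the rendered
    frame and the stripe intervals in µm along x.
    """
    if not (0 <= depletion <= 1):
        raise ValueError(f"depletion must be in [0, 1], got {depletion}")
    if stripe_width_um <= 0 or stripe_period_um <= stripe_width_um:
        raise ValueError("need 0 < stripe_width_um < stripe_period_um")
    rows, cols = config.image_shape
    px = config.pixel_size
    x_um = (np.arange(cols) + 0.5) * px
    phase = np.mod(x_um, stripe_period_um)
    inside = phase < stripe_width_um
    profile = np.where(inside, depletion * high, high)
    img = np.tile(profile, (rows, 1))
    if noise_sd > 0:
        rng = _rng(config.seed, _STREAM_STRIPES)
        img = img + noise_sd * high * rng.standard_normal(img.shape)
    intervals = []
    start = 0.0
    width_total = cols * px
    while start < width_total:
        end = min(start + stripe_width_um, width_total)
        if end > start:
            intervals.append((start, end))
        start += stripe_period_um
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16), intervals


def simulate_spindle_counts(
    seed: int,
    n_embryos: int = 3,
    spindles_per_embryo: int = 50,
    abnormal_rate: float = 0.75,
) -> "pd.DataFrame":
    """Per-embryo normal/abnormal spindle counts with a known abnormal rate.

    Emulates manually classified mitotic phenotypes: each embryo scores
    ``spindles_per_embryo`` spindles, each abnormal independently with
    probability ``abnormal_rate`` (binomial per embryo). Returns a tidy
    count table (embryo_id, category, count).
    """
    if not (0 <= abnormal_rate <= 1):
        raise ValueError(f"abnormal_rate must be in [0, 1], got {abnormal_rate}")
    if n_embryos < 1 or spindles_per_embryo < 1:
        raise ValueError("need at least 1 embryo and 1 spindle per embryo")
    rng = _rng(seed, 5)
    rows = []
    for e in range(n_embryos):
        abnormal = int(rng.binomial(spindles_per_embryo, abnormal_rate))
        rows.append({"embryo_id": e, "category": "abnormal", "count": abnormal})
        rows.append(
            {
                "embryo_id": e,
                "category": "normal",
                "count": spindles_per_embryo - abnormal,
            }
        )
    return pd.DataFrame(rows)
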