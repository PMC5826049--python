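"""Fluorescence-depletion kinetics and axis intensity profiles.

Quantifies protease-mediated GFP depletion two ways: the total-fluorescence
time course of an injected embryo fitted with a plateau exponential
(yielding the depletion half-life), and the intensity profile along a body
axis with a stripe-depletion ratio for striped protease expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .containers import DecaySeries

logger = logging.getLogger(__name__)


@dataclass
class HalfLifeFit:
    i0: float
    i_inf: float
    k: float  # 1/s
    t_half: float | None  # s; None when the fit is flagged
    residual_norm: float
    converged: bool


@dataclass
class IntensityProfile:
    s: np.ndarray  # µm along axis (bin centres)
    intensity: np.ndarray
    band_width: float  # µm


def _frame_background(frame: np.ndarray, n_bins: int = 256) -> float:
    """Background level as the mode of the intensity histogram.

    The mode is robust to the bright foreground (spots, nuclei) occupying
    a minority of pixels.
    """
    hist, edges = np.histogram(frame.ravel(), bins=n_bins)
    j = int(np.argmax(hist))
    return float(0.5 * (edges[j] + edges[j + 1]))


def total_fluorescence(
    stack: np.ndarray,
    t: np.ndarray | None = None,
    dt: float = 1.0,
    background: str | float = "mode",
    roi: tuple[slice, slice] | None = None,
    saturation_level: float | None = None,
    label: str = "",
) -> DecaySeries:
    """Background-subtracted total fluorescence per frame, normalized to I0.

    Background per frame is the histogram mode (``background='mode'``), a
    fixed value, or the mean of a user ROI. The series is normalized to the
    mean of pre-injection frames (t < 0) when the time vector contains
    them, else to the first frame. Saturated frames are flagged via a
    warning log, never silently used.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    n = stack.shape[0]
    t = np.arange(n) * dt if t is None else np.asarray(t, float)
    if len(t) != n:
        raise ValueError("time vector length must match frame count")
    if saturation_level is not None:
        sat = [j for j in range(n) if np.any(stack[j] >= saturation_level)]
        for j in sat:
            logger.warning("frame %d contains saturated pixels", j)
    totals = np.empty(n)
    for j in range(n):
        frame = stack[j]
        if isinstance(background, str):
            if background != "mode":
                raise ValueError(f"unknown background mode {background!r}")
            bg = (
                float(np.mean(frame[roi])) if roi is not None else _frame_background(frame)
            )
        else:
            bg = float(background)
        totals[j] = np.sum(np.clip(frame - bg, 0, None))
    pre = t < 0
    i0 = float(totals[pre].mean()) if pre.any() else float(totals[0])
    if i0 == 0:
        raise ValueError("reference intensity is zero; cannot normalize")
    return DecaySeries(t=t, intensity=totals / i0, i0=i0, label=label)


def _decay_model(t, i_inf, amp, k):
    return i_inf + amp * np.exp(-k * t)


def fit_half_life(series: DecaySeries, plateau: bool = True) -> HalfLifeFit:
    """Nonlinear least-squares fit of I(t) = I_inf + (I0-I_inf) e^{-kt}.

    Initialization: I_inf from the series minimum, I0 from the maximum, k
    from a log-linear regression of the plateau-subtracted intensities.
    ``plateau=False`` pins I_inf at 0 (pure exponential). A fit with k <= 0
    or failed convergence is returned flagged, with t_half = None.
    """
    t = series.t
    y = series.intensity
    if len(t) < 5:
        raise ValueError("need at least 5 time points to fit a decay")
    span = float(t.max() - t.min())
    if span <= 0:
        raise ValueError("degenerate time axis")
    i_inf0 = float(y.min()) if plateau else 0.0
    i00 = float(y.max())
    amp0 = max(i00 - i_inf0, 1e-12)
    shifted = y - i_inf0
    pos = shifted > 0.05 * amp0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(shifted[pos]), 1)[0]
        k0 = max(-float(slope), 1e-6 / span)
    else:
        k0 = 1.0 / span

    try:
        if plateau:
            popt, _ = curve_fit(
                _decay_model, t, y, p0=(i_inf0, amp0, k0), maxfev=10000
            )
            i_inf, amp, k = (float(p) for p in popt)
        else:
            popt, _ = curve_fit(
                lambda tt, amp, k: _decay_model(tt, 0.0, amp, k),
                t, y, p0=(amp0, k0), maxfev=10000,
            )
            amp, k = (float(p) for p in popt)
            i_inf = 0.0
        converged = True
    except RuntimeError:
        i_inf, amp, k = i_inf0, amp0, k0
        converged = False
    resid = y - _decay_model(t, i_inf, amp, k)
    # a decaying amplitude indistinguishable from zero means "no decay"
    ok = converged and k > 0 and amp > 1e-6 * max(float(np.max(np.abs(y))), 1e-300)
    if not ok:
        logger.warning("half-life fit flagged (k=%.3g, converged=%s)", k, converged)
    return HalfLifeFit(
        i0=i_inf + amp,
        i_inf=i_inf,
        k=k,
        t_half=(math.log(2.0) / k) if ok else None,
        residual_norm=float(np.linalg.norm(resid)),
        converged=ok,
    )


def axis_profile(
    image: np.ndarray,
    axis_start: tuple[float, float],
    axis_end: tuple[float, float],
    band_width: float = 10.0,
    n_bins: int = 100,
    pixel_size: float = 1.0,
) -> IntensityProfile:
    """Mean intensity along a body axis, averaged across a band.

    Pixels within ``band_width/2`` (µm) of the segment from ``axis_start``
    to ``axis_end`` (µm, x-y order) are orthogonally projected onto it and
    binned by arclength; the profile is the per-bin mean intensity.
    """
    if band_width <= 0:
        raise ValueError(f"band_width must be > 0, got {band_width}")
    img = np.asarray(image, float)
    rows, cols = img.shape
    p0 = np.asarray(axis_start, float)
    p1 = np.asarray(axis_end, float)
    for p in (p0, p1):
        if not (0 <= p[0] <= cols * pixel_size and 0 <= p[1] <= rows * pixel_size):
            raise ValueError(f"axis endpoint {tuple(p)} outside the image")
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length == 0:
        raise ValueError("axis endpoints coincide")
    u = axis / length

    yy, xx = np.mgrid[0:rows, 0:cols]
    px = (xx + 0.5) * pixel_size - p0[0]
    py = (yy + 0.5) * pixel_size - p0[1]
    along = px * u[0] + py * u[1]
    perp = np.abs(px * (-u[1]) + py * u[0])
    in_band = (perp <= band_width / 2) & (along >= 0) & (along <= length)
    if not in_band.any():
        raise ValueError("no pixel falls inside the axis band")

    edges = np.linspace(0.0, length, n_bins + 1)
    which = np.clip(np.digitize(along[in_band], edges) - 1, 0, n_bins - 1)
    values = img[in_band]
    sums = np.bincount(which, weights=values, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return IntensityProfile(s=centres[keep], intensity=profile[keep], band_width=band_width)


def stripe_depletion(
    profile: IntensityProfile,
    stripe_intervals: list[tuple[float, float]],
) -> dict:
    """Depletion ratio inside expression stripes relative to outside.

    Returns per-stripe ratios (mean intensity inside each interval over the
    mean outside all intervals) and the pooled ratio.
    """
    s = profile.s
    inside = np.zeros(len(s), bool)
    per_stripe = []
    for lo, hi in stripe_intervals:
        if hi <= lo:
            raise ValueError(f"empty stripe interval ({lo}, {hi})")
        mask = (s >= lo) & (s < hi)
        inside |= mask
        per_stripe.append(mask)
    if not inside.any() or inside.all():
        raise ValueError("stripe mask must leave pixels both inside and outside")
    out_mean = float(profile.intensity[~inside].mean())
    if out_mean == 0:
        raise ValueError("outside-stripe intensity is zero")
    ratios = [
        float(profile.intensity[m].mean()) / out_mean if m.any() else float("nan")
        for m in per_stripe
    ]
    pooled = float(profile.intensity[inside].mean()) / out_mean
    return {"per_stripe": ratios, "pooled": pooled, "outside_mean": out_mean}
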