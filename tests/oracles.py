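"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately naive (direct summation, exhaustive geometric
tests, grid search) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving average by direct O(n*w) summation, symmetric truncation."""
    x = np.asarray(x, float)
    n = len(x)
    h = window_samples // 2
    out = np.empty_like(x)
    for j in range(n):
        hj = min(h, j, n - 1 - j)
        acc = 0.0 * x[0]
        for k in range(j - hj, j + hj + 1):
            acc = acc + x[k]
        out[j] = acc / (2 * hj + 1)
    return out


def naive_fluctuation_parameter(
    xy: np.ndarray, dt: float, window_samples: int | None, lag: int = 1
) -> float:
    """Drift-subtracted apparent diffusion by direct computation."""
    xy = np.asarray(xy, float)
    n = len(xy)
    if window_samples is None:
        resid = xy
        valid = np.ones(n, bool)
    else:
        resid = xy - naive_moving_average(xy, window_samples)
        h = window_samples // 2
        valid = np.zeros(n, bool)
        valid[h : n - h] = True
    vals = []
    for j in range(n - lag):
        if valid[j] and valid[j + lag]:
            d = resid[j + lag] - resid[j]
            vals.append(d[0] ** 2 + d[1] ** 2)
    return float(np.mean(vals) / (4.0 * lag * dt))


def _circumcircle(a, b, c):
    """Centre and squared radius of the circle through three points.

    Returns None for (near-)collinear triples.
    """
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = (
        (ax**2 + ay**2) * (by - cy)
        + (bx**2 + by**2) * (cy - ay)
        + (cx**2 + cy**2) * (ay - by)
    ) / d
    uy = (
        (ax**2 + ay**2) * (cx - bx)
        + (bx**2 + by**2) * (ax - cx)
        + (cx**2 + cy**2) * (bx - ax)
    ) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def brute_force_delaunay_edges(points: np.ndarray, eps: float = 1e-9) -> set:
    """Delaunay edges by exhaustive empty-circumcircle testing, O(n^4).

    A triangle (i, j, k) belongs to the Delaunay triangulation iff its
    circumcircle contains no other point strictly inside; its three edges
    are Delaunay edges. Assumes points in general position.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        cc = _circumcircle(pts[i], pts[j], pts[k])
        if cc is None:
            continue
        (ux, uy), r2 = cc
        d2 = (pts[:, 0] - ux) ** 2 + (pts[:, 1] - uy) ** 2
        inside = d2 < r2 - eps * max(r2, 1.0)
        inside[[i, j, k]] = False
        if not inside.any():
            edges.update(
                {tuple(sorted(e)) for e in ((i, j), (j, k), (i, k))}
            )
    return edges


def grid_search_half_life(
    t: np.ndarray,
    y: np.ndarray,
    k_lo: float,
    k_hi: float,
    n_grid: int = 4000,
    plateau: bool = True,
) -> float:
    """Best-fit half-life by dense grid search over the rate constant.

    For each candidate rate k the amplitude (and plateau, unless pinned at
    zero) are solved by linear least squares on the design [1, exp(-k t)];
    the k minimising the residual sum of squares wins.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best_k, best_sse = None, np.inf
    for k in np.geomspace(k_lo, k_hi, n_grid):
        if plateau:
            design = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        else:
            design = np.exp(-k * t)[:, None]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ coef) ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return float(np.log(2.0) / best_k)


def sort_based_quartiles(values) -> tuple[float, float, float]:
    """Quartiles by explicit order statistics with linear interpolation."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(p):
        pos = p * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


def pooled_t_test(a, b) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test from the textbook formula."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * t_dist.sf(abs(t_stat), na + nb - 2)
    return float(t_stat), float(p)
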