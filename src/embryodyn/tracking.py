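"""Spot detection, trajectory linking, and nuclear segmentation.

Coordinate convention (used throughout): 0-based pixel indices, x = column,
y = row, origin at the top-left pixel centre; sub-pixel positions refer to
pixel centres. Linking converts to micrometres via the pixel size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .containers import NuclearArray, TrajectorySet

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISPLACEMENT_PX = 5.0
DEFAULT_MAX_GAP_FRAMES = 2


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float  # column, sub-pixel
    y: float  # row, sub-pixel
    intensity: float


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    """Sub-pixel offset of a 1-D parabola through three samples around a peak."""
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a maximum; keep integer position
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def detect_spots(
    frame: np.ndarray,
    psf_sigma: float,
    threshold: float = 0.3,
    frame_index: int = 0,
) -> list[Detection]:
    """Laplacian-of-Gaussian spot detection with sub-pixel refinement.

    Local maxima of the scale-normalized LoG response above
    ``threshold * max(response)`` are returned; positions are refined by
    quadratic interpolation of the response peak, and detections closer
    than ``psf_sigma`` are merged keeping the brighter one.
    """
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma}")
    img = np.asarray(frame, float)
    if img.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite values")
    resp = -ndi.gaussian_laplace(img, psf_sigma) * psf_sigma**2
    peak = float(resp.max())
    if peak <= 0:
        return []
    coords = peak_local_max(
        resp,
        min_distance=max(1, int(round(psf_sigma))),
        threshold_abs=threshold * peak,
        exclude_border=False,
    )
    rows, cols = resp.shape
    detections = []
    for r, c in coords:
        dy = dx = 0.0
        if 0 < r < rows - 1:
            dy = _quadratic_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
        if 0 < c < cols - 1:
            dx = _quadratic_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
        detections.append(
            Detection(
                frame=frame_index, x=c + dx, y=r + dy, intensity=float(resp[r, c])
            )
        )
    # merge near-duplicates, keeping the brighter detection
    detections.sort(key=lambda d: (-d.intensity, d.y, d.x))
    kept: list[Detection] = []
    for det in detections:
        if all(
            (det.x - k.x) ** 2 + (det.y - k.y) ** 2 >= psf_sigma**2 for k in kept
        ):
            kept.append(det)
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def detect_stack(
    stack: np.ndarray, psf_sigma: float, threshold: float = 0.3
) -> list[list[Detection]]:
    """Run :func:`detect_spots` over every frame of a stack."""
    return [
        detect_spots(frame, psf_sigma, threshold, frame_index=j)
        for j, frame in enumerate(np.asarray(stack))
    ]


def link_detections(
    detections: list[list[Detection]],
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT_PX,
    max_gap: int = DEFAULT_MAX_GAP_FRAMES,
    pixel_size: float = 1.0,
    dt: float = 1.0,
    label: str = "",
) -> TrajectorySet:
    """Greedy globally-nearest-pair frame-to-frame linking.

    Candidate (track end, detection) pairs within ``max_displacement``
    pixels are assigned in order of increasing distance. A track unmatched
    for at most ``max_gap`` frames may resume its id; longer absences start
    a new id. Greedy assignment is deterministic and adequate when spot
    density is low relative to the per-frame step, as for centrosomes in
    the syncytial cortex; it is a declared, replaceable choice.
    """
    if max_displacement <= 0:
        raise ValueError(f"max_displacement must be > 0, got {max_displacement}")
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    rows = []
    next_id = 0
    # active track state: id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    for f, dets in enumerate(detections):
        candidates = []
        for tid, (lf, tx, ty) in active.items():
            if f - lf > max_gap + 1:
                continue
            for k, det in enumerate(dets):
                d = math.hypot(det.x - tx, det.y - ty)
                if d <= max_displacement:
                    candidates.append((d, tid, k))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks, used_dets = set(), set()
        assignment = {}
        for d, tid, k in candidates:
            if tid in used_tracks or k in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(k)
            assignment[k] = tid
        for k, det in enumerate(dets):
            tid = assignment.get(k)
            if tid is None:
                tid = next_id
                next_id += 1
            active[tid] = (f, det.x, det.y)
            rows.append(
                {
                    "particle_id": tid,
                    "frame": f,
                    "t_s": f * dt,
                    "x_um": det.x * pixel_size,
                    "y_um": det.y * pixel_size,
                }
            )
        # drop tracks that can no longer resume
        active = {
            tid: state for tid, state in active.items() if f - state[0] <= max_gap
        }
    data = pd.DataFrame(
        rows, columns=["particle_id", "frame", "t_s", "x_um", "y_um"]
    )
    return TrajectorySet(data=data, dt=dt, pixel_size=pixel_size, label=label)


def segment_nuclei(
    image: np.ndarray,
    smoothing_sigma: float = 2.0,
    min_area: int = 20,
    pixel_size: float = 1.0,
    label: str = "",
) -> NuclearArray:
    """Segment nuclei and return intensity-weighted centroids in µm.

    Pipeline: Gaussian smoothing, Otsu threshold, connected components,
    small-object removal, watershed split of touching nuclei on the
    distance transform.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    empty = NuclearArray(
        data=pd.DataFrame(columns=["nucleus_id", "x_um", "y_um"]),
        bbox=(0.0, img.shape[1] * pixel_size, 0.0, img.shape[0] * pixel_size),
        label=label,
    )
    if np.ptp(img) == 0:
        return empty
    smooth = ndi.gaussian_filter(img, smoothing_sigma)
    mask = smooth > threshold_otsu(smooth)
    if not mask.any():
        return empty
    lab, _ = ndi.label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    mask = sizes[lab] >= int(min_area)
    if not mask.any():
        return empty
    distance = ndi.distance_transform_edt(mask)
    peak_sep = max(2, int(round(2 * smoothing_sigma)))
    marker_coords = peak_local_max(
        distance, min_distance=peak_sep, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, int)
    for i, (r, c) in enumerate(marker_coords, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=mask)
    records = []
    for i, prop in enumerate(regionprops(labels, intensity_image=img)):
        if prop.area < min_area:
            continue
        cy, cx = prop.centroid_weighted
        records.append(
            {
                "nucleus_id": i,
                "x_um": cx * pixel_size,
                "y_um": cy * pixel_size,
            }
        )
    data = pd.DataFrame(records, columns=["nucleus_id", "x_um", "y_um"])
    return NuclearArray(
        data=data,
        bbox=(0.0, img.shape[1] * pixel_size, 0.0, img.shape[0] * pixel_size),
        label=label,
    )
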