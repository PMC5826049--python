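"""Neighbor topology and regularity of the cortical nuclear array.

In interphase the nuclei of the syncytial embryo form a near-hexagonal
array. Its order is quantified by (i) the distribution of neighbor counts
of interior nuclei, binned {<5, 5, 6, 7, >7}, and (ii) the irregularity
parameter sigma/mu: the standard deviation of neighbor-to-neighbor
distances normalized by their mean, 0 for a perfect lattice.

Neighbors are defined through a Delaunay triangulation of the centroids,
with implausibly long edges (hull-spanning artefacts) pruned at a multiple
of the median edge length. Nuclei whose Voronoi cell is unbounded or pokes
outside the convex hull of the observed centroids are flagged as boundary
and excluded from neighbor statistics, since their true neighborhood is
unobserved; the hull criterion (rather than the image rectangle) keeps the
flags invariant under rigid rotation of the field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi

from .containers import NuclearArray

logger = logging.getLogger(__name__)

NEIGHBOR_BINS = ("<5", "5", "6", "7", ">7")
DEFAULT_PRUNE_FACTOR = 2.0


@dataclass
class NeighborGraph:
    """Undirected adjacency over nucleus ids with interior flags."""

    ids: np.ndarray
    points: np.ndarray  # (n, 2) µm, same order as ids
    adjacency: dict  # id -> set of neighbor ids
    distances: dict  # frozenset({id_a, id_b}) -> µm
    interior: dict  # id -> bool

    def neighbor_counts(self, interior_only: bool = True) -> dict:
        return {
            i: len(self.adjacency[i])
            for i in self.ids
            if not interior_only or self.interior[i]
        }

    @property
    def n_interior(self) -> int:
        return sum(bool(v) for v in self.interior.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": self.ids,
                "x_um": self.points[:, 0],
                "y_um": self.points[:, 1],
                "n_neighbors": [len(self.adjacency[i]) for i in self.ids],
                "interior": [bool(self.interior[i]) for i in self.ids],
            }
        )


@dataclass
class RegularityResult:
    """Per-embryo neighbor-count proportions and irregularity sigma/mu."""

    proportions: dict  # bin label -> proportion of interior nuclei
    sigma_over_mu: float
    n_interior: int
    label: str = ""


@dataclass(frozen=True)
class BinComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float


def build_neighbor_graph(
    array: NuclearArray,
    prune_factor: float | None = DEFAULT_PRUNE_FACTOR,
    boundary_margin: float = 0.0,
) -> NeighborGraph:
    """Delaunay neighbor graph with long-edge pruning and boundary flags.

    Edges longer than ``prune_factor`` times the median Delaunay edge
    length are removed (``None`` disables pruning). A nucleus is interior
    iff its Voronoi cell is bounded and lies entirely within the convex
    hull of the centroids, shrunk inward by ``boundary_margin`` (µm).
    """
    pts = array.points
    ids = array.ids
    if len(pts) < 4:
        raise ValueError(f"need at least 4 centroids, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate centroid configuration: {exc}") from exc

    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((int(simplex[a]), int(simplex[b])))
                edges.add((i, j))
    lengths = {e: float(np.linalg.norm(pts[e[0]] - pts[e[1]])) for e in edges}
    if prune_factor is not None:
        cutoff = prune_factor * float(np.median(list(lengths.values())))
        edges = {e for e in edges if lengths[e] <= cutoff}

    adjacency = {i: set() for i in ids}
    distances = {}
    for a, b in edges:
        ia, ib = ids[a], ids[b]
        adjacency[ia].add(ib)
        adjacency[ib].add(ia)
        distances[frozenset((ia, ib))] = lengths[(a, b)]

    vor = Voronoi(pts)
    hull = ConvexHull(pts)
    # hull facet equations a.x + b <= 0 inside; shrink by the margin
    normals = hull.equations[:, :2]
    offsets = hull.equations[:, 2] + boundary_margin
    tol = 1e-9
    interior = {}
    for k, i in enumerate(ids):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) == 0:
            interior[i] = False
            continue
        verts = vor.vertices[region]
        interior[i] = bool(
            np.all(verts @ normals.T + offsets <= tol)
        )
    return NeighborGraph(
        ids=ids, points=pts, adjacency=adjacency, distances=distances,
        interior=interior,
    )


def neighbor_distribution(graph: NeighborGraph) -> dict:
    """Proportion of interior nuclei per neighbor-count bin {<5, 5, 6, 7, >7}."""
    counts = graph.neighbor_counts(interior_only=True)
    if not counts:
        raise ValueError("no interior nuclei: field of view too small")
    props = dict.fromkeys(NEIGHBOR_BINS, 0.0)
    n = len(counts)
    for c in counts.values():
        if c < 5:
            key = "<5"
        elif c > 7:
            key = ">7"
        else:
            key = str(c)
        props[key] += 1.0 / n
    return props


def irregularity(graph: NeighborGraph) -> float:
    """sigma/mu over unique neighbor distances incident to interior nuclei."""
    pooled = [
        d
        for pair, d in graph.distances.items()
        if any(graph.interior[i] for i in pair)
    ]
    if not pooled:
        raise ValueError("no edge touches an interior nucleus")
    if len(pooled) == 1:
        warnings.warn("single interior edge: sigma/mu reported as 0", stacklevel=2)
        return 0.0
    pooled = np.asarray(pooled)
    return float(np.std(pooled, ddof=1) / np.mean(pooled))


def regularity(
    array: NuclearArray,
    prune_factor: float | None = DEFAULT_PRUNE_FACTOR,
    boundary_margin: float = 0.0,
) -> RegularityResult:
    """Full per-embryo regularity summary from a nuclear array."""
    graph = build_neighbor_graph(
        array, prune_factor=prune_factor, boundary_margin=boundary_margin
    )
    return RegularityResult(
        proportions=neighbor_distribution(graph),
        sigma_over_mu=irregularity(graph),
        n_interior=graph.n_interior,
        label=array.label,
    )


def _ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_regularity(
    per_embryo_a: list[RegularityResult],
    per_embryo_b: list[RegularityResult],
) -> dict:
    """Embryo-level two-sided Student's t-tests per bin and for sigma/mu.

    The embryo is the statistical unit (each contributes one proportion per
    bin and one sigma/mu), matching how small-N injected-embryo experiments
    are compared. Returns a dict of bin label (and 'sigma_over_mu') to
    :class:`BinComparison`.
    """
    if len(per_embryo_a) < 2 or len(per_embryo_b) < 2:
        raise ValueError("need at least 2 embryos per condition for a t-test")
    out = {}
    for key in NEIGHBOR_BINS:
        a = np.array([r.proportions[key] for r in per_embryo_a])
        b = np.array([r.proportions[key] for r in per_embryo_b])
        t, p = _ttest(a, b)
        out[key] = BinComparison(
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
            t_statistic=t, p_value=p,
        )
    a = np.array([r.sigma_over_mu for r in per_embryo_a])
    b = np.array([r.sigma_over_mu for r in per_embryo_b])
    t, p = _ttest(a, b)
    out["sigma_over_mu"] = BinComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t_statistic=t, p_value=p,
    )
    return out


def aggregate_proportions(counts: pd.DataFrame) -> dict:
    """Mean +/- s.d. abnormal-category proportion across embryos.

    ``counts`` has columns (embryo_id, category, count) with categories
    'normal' and 'abnormal'. Embryos with zero total are excluded with a
    logged reason; a single remaining embryo reports s.d. 0.
    """
    required = {"embryo_id", "category", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    wide = (
        counts.pivot_table(
            index="embryo_id", columns="category", values="count", aggfunc="sum"
        )
        .reindex(columns=["normal", "abnormal"])
        .fillna(0)
    )
    totals = wide.sum(axis=1)
    excluded = wide.index[totals == 0].tolist()
    for e in excluded:
        logger.info("embryo %r excluded from proportion aggregation: zero total", e)
    wide = wide[totals > 0]
    if wide.empty:
        raise ValueError("no embryo with nonzero counts")
    props = wide["abnormal"] / wide.sum(axis=1)
    sd = float(props.std(ddof=1)) if len(props) > 1 else 0.0
    return {
        "per_embryo": props.to_dict(),
        "mean": float(props.mean()),
        "sd": sd,
        "n_embryos": int(len(props)),
        "pooled_abnormal": int(wide["abnormal"].sum()),
        "pooled_total": int(wide.sum().sum()),
        "excluded_embryos": excluded,
    }
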