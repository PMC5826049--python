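"""Neighbor-graph topology, irregularity and embryo-level comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from embryodyn import nuclear_array as na, synthetic_data as sd
from embryodyn.config import GroundTruth, SimulationConfig
from embryodyn.containers import NuclearArray

from conftest import rotate
from oracles import brute_force_delaunay_edges, pooled_t_test


def graph_edges_by_index(graph):
    """Adjacency as index pairs (ids are indices for generated arrays)."""
    return {
        tuple(sorted(pair)) for pair in (tuple(p) for p in graph.distances)
    }


def jittered_array(seed, n_rows=5, n_cols=5, noise_frac=0.08):
    cfg = SimulationConfig(seed=seed)
    truth = GroundTruth(lattice_spacing=5.0, positional_noise_sd=noise_frac * 5.0)
    return sd.generate_nuclear_array(cfg, truth, n_rows, n_cols)


class TestNeighborGraph:
    def test_perfect_lattice_all_interior_six(self):
        arr = sd.generate_nuclear_array(
            SimulationConfig(seed=0),
            GroundTruth(lattice_spacing=5.0, positional_noise_sd=0.0),
            7,
            7,
        )
        graph = na.build_neighbor_graph(arr)
        counts = graph.neighbor_counts(interior_only=True)
        assert set(counts.values()) == {6}

    def test_symmetry_no_self_edges_and_positive_distances(self):
        graph = na.build_neighbor_graph(jittered_array(1))
        for i, nbrs in graph.adjacency.items():
            assert i not in nbrs
            for j in nbrs:
                assert i in graph.adjacency[j]
        assert all(d > 0 for d in graph.distances.values())

    def test_interior_nuclei_have_at_least_three_neighbors(self):
        graph = na.build_neighbor_graph(jittered_array(2, 8, 8, 0.15))
        for i, c in graph.neighbor_counts(interior_only=True).items():
            assert c >= 3

    def test_adjacency_matches_brute_force_oracle_on_jittered_lattice(self):
        arr = jittered_array(3, 5, 5, 0.1)
        graph = na.build_neighbor_graph(arr, prune_factor=None)
        assert graph_edges_by_index(graph) == brute_force_delaunay_edges(arr.points)

    def test_adjacency_matches_brute_force_oracle_on_random_points(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            pts = rng.uniform(0, 10, size=(18, 2))
            arr = NuclearArray(
                data=pd.DataFrame(
                    {"nucleus_id": range(len(pts)), "x_um": pts[:, 0], "y_um": pts[:, 1]}
                )
            )
            graph = na.build_neighbor_graph(arr, prune_factor=None)
            assert graph_edges_by_index(graph) == brute_force_delaunay_edges(pts)

    def test_degenerate_collinear_input_rejected(self):
        pts = np.stack([np.arange(6.0), np.arange(6.0)], axis=1)
        arr = NuclearArray(
            data=pd.DataFrame(
                {"nucleus_id": range(6), "x_um": pts[:, 0], "y_um": pts[:, 1]}
            )
        )
        with pytest.raises(ValueError, match="degenerate"):
            na.build_neighbor_graph(arr)

    def test_mean_interior_degree_approaches_six(self):
        """Euler's formula: large triangulated arrays average 6 neighbors."""
        graph = na.build_neighbor_graph(jittered_array(5, 20, 20, 0.1))
        counts = list(graph.neighbor_counts(interior_only=True).values())
        assert np.mean(counts) == pytest.approx(6.0, abs=0.2)


class TestDistributionAndIrregularity:
    def test_perfect_lattice_distribution_and_sigma_mu(self):
        graph = na.build_neighbor_graph(
            sd.generate_nuclear_array(
                SimulationConfig(seed=0),
                GroundTruth(lattice_spacing=5.0, positional_noise_sd=0.0),
                9,
                9,
            )
        )
        dist = na.neighbor_distribution(graph)
        assert dist["6"] == pytest.approx(1.0)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert na.irregularity(graph) == pytest.approx(0.0, abs=1e-12)

    def test_deleted_site_drops_neighbor_counts_per_oracle(self):
        arr = jittered_array(6, 7, 7, 0.05)
        graph = na.build_neighbor_graph(arr, prune_factor=None)
        interior_ids = [i for i in graph.ids if graph.interior[i]]
        victim = interior_ids[len(interior_ids) // 2]
        reduced = NuclearArray(
            data=arr.data[arr.data.nucleus_id != victim].reset_index(drop=True),
            bbox=arr.bbox,
        )
        got = na.build_neighbor_graph(reduced, prune_factor=None)
        idx = {nid: k for k, nid in enumerate(reduced.ids)}
        oracle = brute_force_delaunay_edges(reduced.points)
        got_edges = {
            tuple(sorted((idx[a], idx[b])))
            for a, b in (tuple(p) for p in got.distances)
        }
        assert got_edges == oracle
        # the victim's former neighbors lose it from their counts
        for nb in graph.adjacency[victim]:
            assert victim not in got.adjacency.get(nb, set())

    def test_hand_computed_sigma_over_mu(self):
        """Edge lengths {1, 1, 2}: sample s.d. 0.5774 over mean 1.3333."""
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [3.0, 1.0]])
        graph = na.NeighborGraph(
            ids=np.arange(4),
            points=pts,
            adjacency={0: {1}, 1: {0, 2}, 2: {1, 3}, 3: {2}},
            distances={
                frozenset((0, 1)): 1.0,
                frozenset((1, 2)): 1.0,
                frozenset((2, 3)): 2.0,
            },
            interior={0: True, 1: True, 2: True, 3: True},
        )
        assert na.irregularity(graph) == pytest.approx(0.4330, abs=1e-4)

    def test_single_edge_returns_zero_with_warning(self):
        graph = na.NeighborGraph(
            ids=np.arange(2),
            points=np.array([[0.0, 0.0], [1.0, 0.0]]),
            adjacency={0: {1}, 1: {0}},
            distances={frozenset((0, 1)): 1.0},
            interior={0: True, 1: False},
        )
        with pytest.warns(UserWarning, match="single interior edge"):
            assert na.irregularity(graph) == 0.0

    def test_noise_sweep_monotone(self):
        """More positional noise: fewer hexagons, higher sigma/mu."""
        p6, som = [], []
        for frac in (0.0, 0.05, 0.12, 0.2, 0.3):
            res = na.regularity(jittered_array(17, 14, 14, frac))
            p6.append(res.proportions["6"])
            som.append(res.sigma_over_mu)
        assert all(a >= b for a, b in zip(p6, p6[1:]))
        assert all(a < b for a, b in zip(som, som[1:]))

    def test_scale_invariance(self):
        arr = jittered_array(8, 6, 6, 0.1)
        res = na.regularity(arr)
        scaled = NuclearArray(
            data=arr.data.assign(x_um=arr.data.x_um * 3.7, y_um=arr.data.y_um * 3.7)
        )
        res_s = na.regularity(scaled)
        assert res_s.proportions == res.proportions
        assert res_s.sigma_over_mu == pytest.approx(res.sigma_over_mu, rel=1e-12)

    def test_rotation_invariance(self):
        arr = jittered_array(9, 8, 8, 0.08)
        res = na.regularity(arr)
        rot = rotate(arr.points, math.radians(37.0), about=arr.points.mean(axis=0))
        rotated = NuclearArray(
            data=pd.DataFrame(
                {"nucleus_id": arr.ids, "x_um": rot[:, 0], "y_um": rot[:, 1]}
            )
        )
        res_r = na.regularity(rotated)
        assert res_r.n_interior == res.n_interior
        for k in na.NEIGHBOR_BINS:
            assert res_r.proportions[k] == pytest.approx(res.proportions[k], abs=1e-12)
        assert res_r.sigma_over_mu == pytest.approx(res.sigma_over_mu, rel=1e-9)


class TestComparisons:
    @staticmethod
    def _results(values6, sigmas):
        return [
            na.RegularityResult(
                proportions={"<5": 0.0, "5": 1.0 - v, "6": v, "7": 0.0, ">7": 0.0},
                sigma_over_mu=s,
                n_interior=50,
            )
            for v, s in zip(values6, sigmas)
        ]

    def test_identical_conditions_give_t_zero(self):
        a = self._results([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        comp = na.compare_regularity(a, a)
        assert comp["6"].t_statistic == 0.0
        assert comp["sigma_over_mu"].p_value == 1.0

    def test_hand_sized_comparison_matches_textbook_t(self):
        a = self._results([0.52, 0.48, 0.50], [0.20, 0.22, 0.21])
        b = self._results([0.30, 0.35, 0.28], [0.35, 0.33, 0.36])
        comp = na.compare_regularity(a, b)
        t_ref, p_ref = pooled_t_test([0.52, 0.48, 0.50], [0.30, 0.35, 0.28])
        assert comp["6"].t_statistic == pytest.approx(t_ref, rel=1e-12)
        assert comp["6"].p_value == pytest.approx(p_ref, rel=1e-12)

    def test_single_embryo_refused(self):
        a = self._results([0.5], [0.2])
        with pytest.raises(ValueError, match="at least 2 embryos"):
            na.compare_regularity(a, a * 2)


class TestAggregateProportions:
    def test_single_embryo_sd_zero(self):
        counts = pd.DataFrame(
            [
                {"embryo_id": 0, "category": "abnormal", "count": 3},
                {"embryo_id": 0, "category": "normal", "count": 1},
            ]
        )
        agg = na.aggregate_proportions(counts)
        assert agg["mean"] == pytest.approx(0.75)
        assert agg["sd"] == 0.0

    def test_hand_computed_mean_sd(self):
        counts = pd.DataFrame(
            [
                {"embryo_id": e, "category": c, "count": n}
                for e, ab in enumerate((10, 20, 30))
                for c, n in (("abnormal", ab), ("normal", 100 - ab))
            ]
        )
        agg = na.aggregate_proportions(counts)
        assert agg["mean"] == pytest.approx(0.20)
        assert agg["sd"] == pytest.approx(0.10)
        assert agg["pooled_abnormal"] == 60
        assert agg["pooled_total"] == 300

    def test_all_normal_embryos(self):
        counts = pd.DataFrame(
            [
                {"embryo_id": e, "category": c, "count": n}
                for e in range(3)
                for c, n in (("abnormal", 0), ("normal", 40))
            ]
        )
        agg = na.aggregate_proportions(counts)
        assert agg["mean"] == 0.0
        assert agg["sd"] == 0.0

    def test_zero_total_embryo_excluded(self):
        counts = pd.DataFrame(
            [
                {"embryo_id": 0, "category": "abnormal", "count": 0},
                {"embryo_id": 0, "category": "normal", "count": 0},
                {"embryo_id": 1, "category": "abnormal", "count": 5},
                {"embryo_id": 1, "category": "normal", "count": 5},
            ]
        )
        agg = na.aggregate_proportions(counts)
        assert agg["excluded_embryos"] == [0]
        assert agg["n_embryos"] == 1
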