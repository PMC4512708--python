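"""Graph metrics against hand values and brute-force oracles."""

import numpy as np
import pytest

from fconn.construct import threshold_to_density
from fconn.graph_core import DensitySchedule, WeightedGraph
from fconn.metrics import (
    clustering,
    degree_strength,
    global_efficiency,
    metrics_over_schedule,
    minmax_normalize,
    normalized_metrics,
    null_ensemble,
    small_world_index,
)

from conftest import make_graph
from oracles import brute_clustering, brute_efficiency, random_graph


def star_graph(n_leaves: int) -> WeightedGraph:
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = 1.0
    return make_graph(w)


class TestDegreeStrength:
    def test_star_graph(self):
        g = star_graph(5)
        k, s, k_norm, s_norm = degree_strength(g)
        assert k[0] == 5 and np.all(k[1:] == 1)
        assert k_norm[0] == 1.0 and np.all(k_norm[1:] == 0.0)

    def test_path_strengths(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 1.0
        _, s, _, _ = degree_strength(make_graph(w))
        assert np.allclose(s, [0.5, 1.5, 1.0])

    def test_degenerate_normalization_maps_to_one(self):
        g = make_graph(np.ones((4, 4)))
        with pytest.warns(UserWarning, match="degenerate"):
            out = minmax_normalize(g.degrees())
        assert np.all(out == 1.0)


class TestClustering:
    def test_uniform_complete_graph(self):
        c, c_glob = clustering(make_graph(np.ones((5, 5))))
        assert np.allclose(c, 1.0)
        assert c_glob == pytest.approx(1.0)

    def test_hand_triangle(self, triangle):
        # max-scaled weights 1, 0.5, 0.25 -> geometric mean 0.5 at every node
        c, c_glob = clustering(triangle)
        assert np.allclose(c, 0.5)
        assert c_glob == pytest.approx(0.5)

    def test_star_has_no_triangles(self):
        c, c_glob = clustering(star_graph(6))
        assert np.all(c == 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            w = random_graph(rng, rng.integers(3, 9))
            got, _ = clustering(make_graph(w))
            assert np.allclose(got, brute_clustering(w), atol=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            c, _ = clustering(make_graph(random_graph(rng, 8)))
            assert np.all((c >= 0) & (c <= 1 + 1e-12))


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        assert global_efficiency(make_graph(np.ones((6, 6)))) == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        # pair distances 1, 1, 2 -> (1 + 1 + 0.5) / 3
        assert global_efficiency(make_graph(w)) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_disconnected_pairs_contribute_zero(self):
        assert global_efficiency(make_graph(np.zeros((2, 2)))) == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            w = random_graph(rng, rng.integers(3, 9), p_edge=0.5)
            assert global_efficiency(make_graph(w)) == pytest.approx(
                brute_efficiency(w), abs=1e-10
            )

    def test_bounded_by_one_for_unit_weights(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            e = global_efficiency(make_graph(random_graph(rng, 8)))
            assert 0.0 <= e <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def medium_graph():
    rng = np.random.default_rng(33)
    m = np.triu(rng.uniform(0.1, 1.0, (40, 40)), 1)
    g = WeightedGraph(tuple(f"n{i}" for i in range(40)), m + m.T)
    return threshold_to_density(g, 0.4)


class TestNullEnsemble:
    def test_degree_sequence_and_weights_preserved(self, medium_graph):
        nulls = null_ensemble(medium_graph, count=5, seed=3)
        iu = np.triu_indices(medium_graph.n_nodes, 1)
        w0 = np.sort(medium_graph.weights[iu])
        d0 = np.sort(medium_graph.degrees())
        for nl in nulls:
            assert np.array_equal(np.sort(nl.degrees()), d0)
            assert np.allclose(np.sort(nl.weights[iu]), w0)

    def test_strength_approximately_preserved_with_hubs(self):
        # planted-hub graph: a few nodes with far higher strength
        rng = np.random.default_rng(8)
        n = 50
        m = np.triu(rng.uniform(0.05, 0.3, (n, n)), 1)
        m[:3, :] *= 3.0  # rows 0-2 become hubs
        m = np.triu(m, 1)
        g = threshold_to_density(make_graph(m + m.T), 0.5)
        s0 = g.strengths()
        nulls = null_ensemble(g, count=30, seed=4)
        err = np.mean(
            [np.mean(np.abs(nl.strengths() - s0) / s0) for nl in nulls]
        )
        assert err < 0.10

    def test_complete_graph_falls_back_with_warning(self):
        g = make_graph(np.ones((5, 5)) * 0.7)
        with pytest.warns(UserWarning, match="rewiring"):
            nulls = null_ensemble(g, count=2, seed=1)
        assert len(nulls) == 2

    def test_deterministic_given_seed(self, medium_graph):
        a = null_ensemble(medium_graph, count=2, seed=9)
        b = null_ensemble(medium_graph, count=2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)


class TestSmallWorldIndex:
    def test_formula(self):
        assert small_world_index(1.0, 1.0) == 1.0
        assert small_world_index(1.56, 1.0) == pytest.approx(1.56)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            small_world_index(0.0, 1.0)

    def test_self_normalization_identity(self, medium_graph):
        _, c = clustering(medium_graph)
        e = global_efficiency(medium_graph)
        assert small_world_index(c / c, e / e) == pytest.approx(1.0)

    def test_lattice_plus_shortcuts_is_small_world(self):
        # ring lattice (k=4 neighbours) with a few random shortcuts
        rng = np.random.default_rng(17)
        n = 60
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        for _ in range(12):
            i, j = rng.integers(0, n, 2)
            if i != j:
                w[i, j] = w[j, i] = 1.0
        g = make_graph(w)
        _, _, sigma = normalized_metrics(g, nulls=20, seed=2)
        assert sigma > 1.0


class TestMetricsOverSchedule:
    def test_reports_echo_densities_and_are_deterministic(self, medium_graph):
        schedule = DensitySchedule((0.2, 0.3, 0.4))
        graphs = [threshold_to_density(medium_graph, d) for d in schedule]
        r1 = metrics_over_schedule(graphs, schedule, nulls=5, seed=11)
        r2 = metrics_over_schedule(graphs, schedule, nulls=5, seed=11)
        assert [r.density for r in r1] == [0.2, 0.3, 0.4]
        assert [r.sigma for r in r1] == [r.sigma for r in r2]

    def test_clustering_nondecreasing_for_nested_homogeneous_graphs(self):
        # nested thresholdings of a homogeneous-weight graph: each added
        # density level closes triangles faster than the degree term grows
        rng = np.random.default_rng(12)
        n = 40
        base = np.triu(rng.uniform(0.5, 1.0, (n, n)), 1)
        g = make_graph(base + base.T)
        schedule = DensitySchedule((0.3, 0.5, 0.7))
        graphs = [threshold_to_density(g, d) for d in schedule]
        reports = metrics_over_schedule(graphs, schedule, nulls=0)
        cs = [r.global_clustering for r in reports]
        assert cs == sorted(cs)
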