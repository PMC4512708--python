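"""Network construction: correlation, thresholding, elimination, averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fconn.construct import (
    apply_schedule,
    correlation_graph,
    density,
    eliminate_nodes,
    group_average,
    random_network_control,
    threshold_to_density,
)
from fconn.graph_core import (
    DensitySchedule,
    RoiLabelTable,
    RoiTimeSeriesPanel,
    WeightedGraph,
)

from conftest import make_graph


def panel_from_columns(cols: dict[str, list[float]]) -> RoiTimeSeriesPanel:
    names = list(cols)
    labels = RoiLabelTable(
        pd.DataFrame(
            {
                "region_name": names,
                "hemisphere": ["L"] * len(names),
                "tissue_class": ["cortical"] * len(names),
                "atlas_index": range(1, len(names) + 1),
            }
        )
    )
    data = np.array(list(cols.values()), dtype=float).T
    return RoiTimeSeriesPanel("s1", "rest", data, labels)


class TestCorrelationGraph:
    def test_perfect_correlation(self):
        p = panel_from_columns({"x": [1, 2, 3, 4], "y": [2, 4, 6, 8]})
        g = correlation_graph(p)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_clamped(self):
        p = panel_from_columns({"x": [1, 2, 3, 4], "y": [-1, -2, -3, -4]})
        g = correlation_graph(p)
        assert g.weights[0, 1] == 0.0
        assert g.negative_count == 1

    def test_hand_computed_pearson(self):
        # deviations (-1.5,-.5,.5,1.5) vs (-1.5,.5,-.5,1.5):
        # r = sum xy / sqrt(sum x^2 * sum y^2) = 4.0 / 5.0
        p = panel_from_columns({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        g = correlation_graph(p)
        assert g.weights[0, 1] == pytest.approx(4.0 / 5.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50),
        offset=st.floats(-100, 100),
    )
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 4))
        labels = [f"r{i}" for i in range(4)]
        p1 = panel_from_columns(dict(zip(labels, base.T)))
        rescaled = base.copy()
        rescaled[:, 0] = scale * rescaled[:, 0] + offset
        p2 = panel_from_columns(dict(zip(labels, rescaled.T)))
        assert np.allclose(
            correlation_graph(p1).weights, correlation_graph(p2).weights, atol=1e-10
        )


class TestDensity:
    def test_complete_graph(self, two_cliques):
        w = np.ones((4, 4))
        g = make_graph(w)
        assert density(g) == 1.0

    def test_counted_fraction(self):
        # 150 nodes, 6705 edges -> 6705 / 11175 = 0.6
        rng = np.random.default_rng(0)
        n = 150
        iu = np.triu_indices(n, 1)
        w = np.zeros((n, n))
        chosen = rng.choice(iu[0].size, size=6705, replace=False)
        w[iu[0][chosen], iu[1][chosen]] = rng.uniform(0.1, 1, 6705)
        g = make_graph(w + w.T)
        assert density(g) == pytest.approx(0.60)

    def test_edgeless(self):
        assert density(make_graph(np.zeros((5, 5)))) == 0.0


class TestThresholdToDensity:
    def test_sort_and_cut(self):
        w = np.zeros((4, 4))
        vals = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = next(vals)
        g = make_graph(w)
        cut = threshold_to_density(g, 0.5)
        kept = sorted(wt for _, _, wt in cut.edge_list())
        assert kept == [0.7, 0.8, 0.9]
        assert density(cut) == pytest.approx(0.5)

    def test_identity_at_current_density(self, triangle):
        out = threshold_to_density(triangle, density(triangle))
        assert np.allclose(out.weights, triangle.weights)

    def test_target_above_density_rejected(self, triangle):
        sparse = threshold_to_density(triangle, 1 / 3)
        with pytest.raises(ValueError):
            threshold_to_density(sparse, 0.9)

    def test_tie_break_lexicographic(self):
        w = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = 0.5  # all tied
        g = make_graph(w)
        cut = threshold_to_density(g, 0.5)
        assert [(i, j) for i, j, _ in cut.edge_list()] == [(0, 1), (0, 2), (0, 3)]
        assert density(cut) <= 0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 0.9))
    def test_never_increases_weights_or_adds_edges(self, seed, target):
        from oracles import random_graph

        rng = np.random.default_rng(seed)
        g = make_graph(random_graph(rng, 8, p_edge=0.9))
        if target > density(g):
            return
        cut = threshold_to_density(g, target)
        assert np.all(cut.weights <= g.weights + 1e-15)
        assert np.all((cut.weights > 0) <= (g.weights > 0))


class TestEliminateNodes:
    def test_isolated_node_removed(self):
        # node 5's edges are all weakest; after the 50% cut it keeps no links
        w = np.zeros((6, 6))
        strong = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (0, 4), (1, 4)]
        for a, b in strong:
            w[a, b] = w[b, a] = 0.9
        w[5, 0] = w[0, 5] = 0.01
        g = make_graph(w)
        keep = eliminate_nodes([g], target_density=7 / 15, min_degree_frac=0.05)
        assert "n5" not in keep
        assert len(keep) == 5

    def test_all_nodes_kept_when_well_connected(self, two_cliques):
        w = np.ones((6, 6))
        g = make_graph(w)
        keep = eliminate_nodes([g], target_density=0.5, min_degree_frac=0.05)
        assert len(keep) == 6

    def test_planted_weak_nodes_removed_in_large_panel(self):
        # 212-node reference with 62 planted weak nodes -> 150 retained
        rng = np.random.default_rng(42)
        n, n_weak = 212, 62
        w = rng.uniform(0.4, 1.0, size=(n, n))
        w = (w + w.T) / 2
        weak = rng.choice(n, size=n_weak, replace=False)
        w[weak, :] *= 0.01
        w[:, weak] *= 0.01
        np.fill_diagonal(w, 0)
        g = make_graph(w)
        keep = eliminate_nodes([g], target_density=0.5, min_degree_frac=0.05)
        assert len(keep) == n - n_weak == 150
        assert not set(f"n{i}" for i in weak) & set(keep)


class TestRandomNetworkControl:
    def test_downsizing_preserves_degree_distribution_shape(self):
        rng = np.random.default_rng(3)
        graphs = []
        for _ in range(4):
            w = np.where(rng.random((50, 50)) < 0.7, rng.uniform(0.1, 1, (50, 50)), 0)
            w = np.triu(w, 1)
            graphs.append(make_graph(w + w.T))
        report = random_network_control(graphs, 0.5, 0.05, seed=9)
        assert report.cv_relative_change < 0.20

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        w = np.triu(rng.uniform(0.1, 1, (30, 30)), 1)
        graphs = [make_graph(w + w.T)]
        r1 = random_network_control(graphs, 0.5, 0.05, seed=5)
        r2 = random_network_control(graphs, 0.5, 0.05, seed=5)
        assert r1 == r2

    def test_zero_edge_surrogate_errors(self):
        with pytest.raises(ValueError):
            random_network_control([make_graph(np.zeros((5, 5)))], 0.5, 0.05, 1)


class TestGroupAverage:
    def test_identical_graphs_unchanged(self, triangle):
        avg = group_average([triangle, triangle])
        assert np.allclose(avg.weights, triangle.weights)

    def test_consensus_rule_drops_partial_edges(self):
        w1 = np.zeros((3, 3))
        w1[0, 1] = w1[1, 0] = 0.8
        w2 = np.zeros((3, 3))
        w2[1, 2] = w2[2, 1] = 0.6
        avg = group_average([make_graph(w1), make_graph(w2)], min_presence=1.0)
        assert avg.n_edges == 0

    def test_mean_weight(self):
        w1 = np.zeros((3, 3))
        w1[0, 1] = w1[1, 0] = 0.4
        w2 = np.zeros((3, 3))
        w2[0, 1] = w2[1, 0] = 0.6
        avg = group_average([make_graph(w1), make_graph(w2)])
        assert avg.weights[0, 1] == pytest.approx(0.5)

    def test_group_density_bounded_by_inputs(self):
        rng = np.random.default_rng(11)
        mats = [np.triu(rng.uniform(0.1, 1, (20, 20)), 1) for _ in range(4)]
        graphs = [threshold_to_density(make_graph(m + m.T), 0.8) for m in mats]
        avg = group_average(graphs, min_presence=1.0)
        assert density(avg) <= 0.8 + 1e-12


class TestApplySchedule:
    def test_nested_edge_sets(self):
        rng = np.random.default_rng(13)
        m = np.triu(rng.uniform(0.1, 1, (30, 30)), 1)
        g = make_graph(m + m.T)
        schedule = DensitySchedule.linear(0.60, 0.78, 10)
        graphs = apply_schedule(g, schedule)
        assert len(graphs) == 10
        for lo, hi in zip(graphs, graphs[1:]):
            assert np.all((lo.weights > 0) <= (hi.weights > 0))

    def test_full_density_identity(self):
        g = make_graph(np.ones((4, 4)))
        out = apply_schedule(g, DensitySchedule((1.0,)))
        assert np.allclose(out[0].weights, g.weights)

    def test_infeasible_schedule_names_density(self, triangle):
        sparse = threshold_to_density(triangle, 0.4)
        with pytest.raises(ValueError, match="0.9"):
            apply_schedule(sparse, DensitySchedule((0.9,)))
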