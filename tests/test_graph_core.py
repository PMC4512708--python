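"""Domain-type invariants and file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import scipy.io

from fconn import io
from fconn.graph_core import (
    DensitySchedule,
    FormatError,
    LabelError,
    Partition,
    PermutationResult,
    RoiLabelTable,
    RoiTimeSeriesPanel,
    SymmetryError,
    WeightedGraph,
    canonicalize_assignment,
)


class TestWeightedGraph:
    def test_symmetrizes_and_zeroes_diagonal(self):
        w = np.array([[1.0, 0.5], [0.5 + 1e-10, 2.0]])
        g = WeightedGraph(("a", "b"), w)
        assert g.weights[0, 0] == 0.0
        assert g.weights[0, 1] == pytest.approx(0.5, abs=1e-9)
        assert np.array_equal(g.weights, g.weights.T)

    def test_asymmetry_beyond_tolerance_rejected(self):
        w = np.array([[0.0, 0.5], [0.6, 0.0]])
        with pytest.raises(SymmetryError):
            WeightedGraph(("a", "b"), w)

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -0.5], [-0.5, 0.0]])
        with pytest.raises(ValueError):
            WeightedGraph(("a", "b"), w)

    def test_nonsquare_rejected(self):
        with pytest.raises(FormatError):
            WeightedGraph(("a", "b"), np.zeros((2, 3)))

    def test_subgraph_preserves_weights(self, triangle):
        sub = triangle.subgraph(["a", "c"])
        assert sub.weights[0, 1] == pytest.approx(0.4)
        with pytest.raises(LabelError):
            triangle.subgraph(["a", "zzz"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            (5, 5),
            elements=st.floats(0, 1, allow_nan=False),
        )
    )
    def test_construction_postconditions(self, raw):
        sym = (raw + raw.T) / 2
        g = WeightedGraph(tuple("abcde"), sym)
        assert np.array_equal(g.weights, g.weights.T)
        assert (g.weights >= 0).all()
        assert np.all(np.diag(g.weights) == 0)


class TestLabelTable:
    def test_duplicate_names_rejected(self):
        df = pd.DataFrame(
            {
                "region_name": ["A", "A"],
                "hemisphere": ["L", "R"],
                "tissue_class": ["cortical", "cortical"],
                "atlas_index": [1, 2],
            }
        )
        with pytest.raises(LabelError):
            RoiLabelTable(df)

    def test_unknown_hemisphere_rejected(self):
        df = pd.DataFrame(
            {
                "region_name": ["A"],
                "hemisphere": ["X"],
                "tissue_class": ["cortical"],
                "atlas_index": [1],
            }
        )
        with pytest.raises(LabelError):
            RoiLabelTable(df)


class TestTimeSeriesPanel:
    def test_constant_column_rejected(self, labels3):
        data = np.random.default_rng(0).normal(size=(10, 3))
        data[:, 1] = 5.0
        with pytest.raises(FormatError, match="constant"):
            RoiTimeSeriesPanel("s1", "rest", data, labels3)

    def test_too_few_timepoints_rejected(self, labels3):
        with pytest.raises(FormatError):
            RoiTimeSeriesPanel("s1", "rest", np.ones((2, 3)), labels3)


class TestPartition:
    def test_canonical_anchoring(self):
        assert list(canonicalize_assignment([2, 2, 1, 1])) == [1, 1, 2, 2]
        assert list(canonicalize_assignment([3, 1, 3, 2])) == [1, 2, 1, 3]

    def test_gap_ids_relabelled(self):
        with pytest.warns(UserWarning):
            p = Partition(np.array([1, 3, 3, 1]))
        assert list(p.assignment) == [1, 2, 2, 1]
        assert p.m == 2

    def test_singletons(self):
        p = Partition.singletons(4)
        assert list(p.assignment) == [1, 2, 3, 4]
        assert p.m == 4


class TestDensitySchedule:
    def test_must_increase(self):
        with pytest.raises(ValueError):
            DensitySchedule((0.6, 0.6))
        with pytest.raises(ValueError):
            DensitySchedule((0.5, 1.2))

    def test_linear(self):
        s = DensitySchedule.linear(0.60, 0.78, 10)
        assert len(s) == 10
        assert s.densities[0] == pytest.approx(0.60)
        assert s.densities[-1] == pytest.approx(0.78)


class TestPermutationResult:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            PermutationResult(
                ("a", "b"),
                t_observed=np.array([5.0, 1.0]),
                p_corrected=np.array([0.9, 0.1]),
                n_permutations=100,
                seed=0,
            )


class TestMatrixIO:
    def test_headered_round_trip(self, tmp_path, triangle):
        path = tmp_path / "m.tsv"
        io.write_matrix(triangle, path)
        back = io.read_matrix(path)
        assert back.node_labels == triangle.node_labels
        assert np.allclose(back.weights, triangle.weights)

    def test_trivial_offdiagonal_read(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("1,0.5,0.5\n0.5,1,0.5\n0.5,0.5,1\n")
        labels = RoiLabelTable(
            pd.DataFrame(
                {
                    "region_name": ["A", "B", "C"],
                    "hemisphere": ["L", "L", "L"],
                    "tissue_class": ["cortical"] * 3,
                    "atlas_index": [1, 2, 3],
                }
            )
        )
        g = io.read_matrix(path, labels)
        assert g.n_edges == 3
        assert np.all(g.weights[np.triu_indices(3, 1)] == 0.5)

    def test_negative_entry_clamped_and_counted(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\tA\tB\nA\t0\t-0.2\nB\t-0.2\t0\n")
        with pytest.warns(UserWarning, match="negative"):
            g = io.read_matrix(path)
        assert g.weights[0, 1] == 0.0
        assert g.negative_count == 1

    def test_nonsquare_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("1\t2\t3\t4\n5\t6\t7\t8\n9\t1\t2\t3\n")
        with pytest.raises((FormatError, LabelError)):
            io.read_matrix(path)

    def test_matlab_container(self, tmp_path, triangle):
        path = tmp_path / "m.mat"
        scipy.io.savemat(path, {"conn": np.asarray(triangle.weights)})
        g = io.read_matrix(path)
        assert np.allclose(g.weights, triangle.weights)

    def test_label_mismatch_rejected(self, tmp_path, triangle, labels3):
        path = tmp_path / "m.tsv"
        io.write_matrix(triangle, path)  # labels a, b, c
        with pytest.raises(LabelError):
            io.read_matrix(path, labels3)  # expects A, B, C


class TestPartitionIO:
    def test_round_trip(self, tmp_path):
        p = Partition(np.array([1, 1, 2, 2]))
        path = tmp_path / "p.tsv"
        io.write_partition(p, path, ["a", "b", "c", "d"])
        back, nodes = io.read_partition(path)
        assert list(back.assignment) == [1, 1, 2, 2]
        assert nodes == ["a", "b", "c", "d"]

    def test_noncanonical_file_canonicalized(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("node\tmodule\na\t2\nb\t2\nc\t1\nd\t1\n")
        with pytest.warns(UserWarning):
            p, _ = io.read_partition(path)
        assert list(p.assignment) == [1, 1, 2, 2]

    def test_gap_ids_relabelled(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("node\tmodule\na\t1\nb\t3\n")
        with pytest.warns(UserWarning):
            p, _ = io.read_partition(path)
        assert list(p.assignment) == [1, 2]


class TestLabelAndSeriesIO:
    def test_label_round_trip(self, tmp_path, labels3):
        path = tmp_path / "labels.tsv"
        io.write_label_table(labels3, path)
        back = io.read_label_table(path)
        assert back.region_names == labels3.region_names

    def test_timeseries_round_trip(self, tmp_path, labels3):
        rng = np.random.default_rng(1)
        panel = RoiTimeSeriesPanel("s1", "rest", rng.normal(size=(20, 3)), labels3)
        path = tmp_path / "s1_rest.tsv"
        io.write_timeseries(panel, path)
        back = io.read_timeseries(path, labels3, "s1", "rest")
        assert np.allclose(back.data, panel.data, atol=1e-6)
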