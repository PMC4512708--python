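import numpy as np
import pandas as pd
import pytest

from fconn.graph_core import Partition, RoiLabelTable, WeightedGraph


@pytest.fixture
def labels3():
    return RoiLabelTable(
        pd.DataFrame(
            {
                "region_name": ["A", "B", "C"],
                "hemisphere": ["L", "R", "midline"],
                "tissue_class": ["cortical", "subcortical", "cerebellar"],
                "atlas_index": [1, 2, 3],
            }
        )
    )


@pytest.fixture
def triangle():
    """Single triangle with weights 0.8, 0.4, 0.2."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.8
    w[0, 2] = w[2, 0] = 0.4
    w[1, 2] = w[2, 1] = 0.2
    return WeightedGraph(("a", "b", "c"), w)


@pytest.fixture
def two_cliques():
    """Two disjoint unit-weight 3-cliques; optimal partition has Q = 0.5."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[a, b] = w[b, a] = 1.0
    return WeightedGraph(tuple("abcdef"), w)


@pytest.fixture
def clique_partition():
    return Partition(np.array([1, 1, 1, 2, 2, 2]))


def make_graph(w: np.ndarray) -> WeightedGraph:
    return WeightedGraph(tuple(f"n{i}" for i in range(w.shape[0])), w)
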