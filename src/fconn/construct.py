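"""Network construction: correlation graphs, density thresholding, nodal
elimination against a reference condition, and group averaging.

The construction recipe mirrors a standard functional-connectomics pipeline:
zero-lag Pearson correlations between ROI time series become edge weights
(negative correlations removed), each subject network is proportionally
thresholded to a target density, weakly attached nodes are eliminated using a
single reference condition and the same node set is imposed on every other
condition, and group networks are formed by a consensus average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph_core import DensitySchedule, RoiTimeSeriesPanel, WeightedGraph

__all__ = [
    "correlation_graph",
    "density",
    "threshold_to_density",
    "eliminate_nodes",
    "random_network_control",
    "group_average",
    "apply_schedule",
]


def correlation_graph(panel: RoiTimeSeriesPanel) -> WeightedGraph:
    """Pearson correlation network of a time-series panel.

    Edge weight = max(0, r_ij): negative correlations are removed, the
    diagonal is zeroed.
    """
    r = np.corrcoef(panel.data, rowvar=False)
    neg = int(np.count_nonzero(np.triu(r, k=1) < 0))
    w = np.clip(r, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(
        tuple(panel.roi_labels.region_names), w, negative_count=neg
    )


def density(graph: WeightedGraph) -> float:
    """Fraction of realized edges out of all N(N-1)/2 possible pairs."""
    n = graph.n_nodes
    return graph.n_edges / (n * (n - 1) / 2)


def _ranked_edges(graph: WeightedGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive edges sorted by descending weight, ties by (i, j) ascending."""
    i, j = np.triu_indices(graph.n_nodes, k=1)
    w = graph.weights[i, j]
    keep = w > 0
    i, j, w = i[keep], j[keep], w[keep]
    order = np.lexsort((j, i, -w))
    return i[order], j[order], w[order]


def threshold_to_density(graph: WeightedGraph, target: float) -> WeightedGraph:
    """Keep the floor(target * N(N-1)/2) highest-weight edges.

    Ties at the cut weight are broken by lexicographic node-pair order so the
    result is deterministic; kept weights are unchanged, so the operation
    never increases any weight and never adds edges.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError(f"target density {target} outside (0, 1]")
    current = density(graph)
    if target > current + 1e-12:
        raise ValueError(
            f"target density {target:.4f} above current density {current:.4f}; "
            "thresholding cannot add edges"
        )
    n = graph.n_nodes
    n_keep = int(np.floor(target * n * (n - 1) / 2))
    i, j, w = _ranked_edges(graph)
    out = np.zeros_like(graph.weights)
    out[i[:n_keep], j[:n_keep]] = w[:n_keep]
    out = out + out.T
    return WeightedGraph(graph.node_labels, out)


def eliminate_nodes(
    reference_graphs: list[WeightedGraph],
    target_density: float = 0.5,
    min_degree_frac: float = 0.05,
) -> list[str]:
    """Two-stage nodal elimination on a reference condition.

    The across-subject mean reference matrix is thresholded to
    ``target_density`` and nodes retaining fewer than
    ``min_degree_frac * (N - 1)`` links are dropped. The returned keep-list is
    meant to be applied identically to every other condition so all networks
    share one node set.
    """
    if not reference_graphs:
        raise ValueError("no reference graphs")
    labels = reference_graphs[0].node_labels
    for g in reference_graphs[1:]:
        if g.node_labels != labels:
            raise ValueError("reference graphs must share the node set")
    mean_w = np.mean([g.weights for g in reference_graphs], axis=0)
    mean_graph = WeightedGraph(labels, mean_w)
    thresholded = threshold_to_density(mean_graph, target_density)
    degrees = thresholded.degrees()
    floor = min_degree_frac * (len(labels) - 1)
    keep = [lab for lab, k in zip(labels, degrees) if k >= floor]
    if not keep:
        raise ValueError("elimination removed every node")
    sub = thresholded.subgraph(keep)
    if _n_components(sub) > 1:
        warnings.warn("retained node set is disconnected", stacklevel=2)
    return keep


def _n_components(graph: WeightedGraph) -> int:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components((graph.weights > 0).astype(int), directed=False)
    return n


@dataclass(frozen=True)
class EliminationControlReport:
    """Degree-distribution comparison of full vs downsized random surrogates."""

    n_surrogates: int
    n_nodes_full: int
    n_nodes_downsized: int
    cv_degree_full: float
    cv_degree_downsized: float
    mean_degree_full: float
    mean_degree_downsized: float
    seed: int

    @property
    def cv_relative_change(self) -> float:
        if self.cv_degree_full == 0:
            return 0.0
        return abs(self.cv_degree_downsized - self.cv_degree_full) / self.cv_degree_full


def random_network_control(
    reference_graphs: list[WeightedGraph],
    target_density: float = 0.5,
    min_degree_frac: float = 0.05,
    seed: int = 0,
) -> EliminationControlReport:
    """Validity check of the elimination strategy on random surrogates.

    Builds per-subject surrogate networks with the same number of nonzero
    entries as the originals but randomized topology and shuffled weights,
    repeats the elimination on them, and compares the degree-distribution
    shape (coefficient of variation) of the downsized surrogates against the
    full ones. An elimination strategy that preserves topological structure
    leaves the shape essentially unchanged.
    """
    rng = np.random.default_rng(seed)
    labels = reference_graphs[0].node_labels
    n = len(labels)
    surrogates = []
    for g in reference_graphs:
        i, j = np.triu_indices(n, k=1)
        w = g.weights[i, j]
        vals = w[w > 0]
        if vals.size == 0:
            raise ValueError("surrogate source graph has zero edges")
        pos = rng.choice(i.size, size=vals.size, replace=False)
        flat = np.zeros(i.size)
        flat[pos] = rng.permutation(vals)
        m = np.zeros((n, n))
        m[i, j] = flat
        surrogates.append(WeightedGraph(labels, m + m.T))

    mean_full = WeightedGraph(
        labels, np.mean([s.weights for s in surrogates], axis=0)
    )
    full_deg = threshold_to_density(mean_full, target_density).degrees()
    keep = eliminate_nodes(surrogates, target_density, min_degree_frac)
    down = threshold_to_density(
        mean_full.subgraph(keep), min(target_density, density(mean_full.subgraph(keep)))
    ).degrees()

    def cv(x: np.ndarray) -> float:
        return float(np.std(x) / np.mean(x)) if np.mean(x) > 0 else 0.0

    return EliminationControlReport(
        n_surrogates=len(surrogates),
        n_nodes_full=n,
        n_nodes_downsized=len(keep),
        cv_degree_full=cv(full_deg),
        cv_degree_downsized=cv(down),
        mean_degree_full=float(np.mean(full_deg)),
        mean_degree_downsized=float(np.mean(down)),
        seed=seed,
    )


def group_average(
    graphs: list[WeightedGraph], min_presence: float = 1.0
) -> WeightedGraph:
    """Consensus group average: keep an edge iff present in at least
    ``min_presence`` of subjects; its weight is the mean across all subjects.

    With ``min_presence = 1`` (every subject must show the edge) the group
    density can only fall below the per-subject densities, which is why
    subject networks thresholded to a higher density yield a sparser group
    network.
    """
    if not graphs:
        raise ValueError("no graphs to average")
    if not (0.0 < min_presence <= 1.0):
        raise ValueError("min_presence must lie in (0, 1]")
    labels = graphs[0].node_labels
    for g in graphs[1:]:
        if g.node_labels != labels:
            raise ValueError("graphs must share the node set")
    stack = np.stack([g.weights for g in graphs])
    presence = (stack > 0).mean(axis=0)
    mean_w = stack.mean(axis=0)
    out = np.where(presence >= min_presence - 1e-12, mean_w, 0.0)
    return WeightedGraph(labels, out)


def apply_schedule(
    graph: WeightedGraph, schedule: DensitySchedule
) -> list[WeightedGraph]:
    """Threshold one graph to each density of the schedule.

    The results are nested: the edge set at a lower density is a subset of
    the edge set at any higher density.
    """
    current = density(graph)
    for d in schedule:
        if d > current + 1e-12:
            raise ValueError(
                f"scheduled density {d:.4f} exceeds graph density {current:.4f}"
            )
    return [threshold_to_density(graph, d) for d in schedule]
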