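"""Community detection by Kernighan–Lin-style modularity refinement,
consensus affiliation over repeated runs, and partition comparison by
normalized mutual information.

Weighted Newman modularity of a partition into modules m:

    Q = sum_m [ W_m / W  -  (S_m / 2W)^2 ]

with W the total edge weight (each edge counted once), W_m the intra-module
weight and S_m the summed strength of module m's nodes. The refinement starts
from the all-singleton partition M0 = (1, ..., N) and sweeps nodes in seeded
random order, moving each node to the neighbouring (or a fresh singleton)
module with the largest positive modularity gain until a full sweep yields no
improvement. Because single moves are stochastic in order, the refinement is
repeated many times in a chain (each run seeding the next) and the final
affiliation is the node-wise modal module id over the canonicalized chain,
with node #1 anchoring module 1.

The partition distance p_d used here is the normalized mutual information
2 I(X;Y) / (H(X) + H(Y)); despite the word "distance", larger values mean
more similar partitions.
"""

from __future__ import annotations

import numpy as np

from .graph_core import Partition, WeightedGraph, canonicalize_assignment

__all__ = [
    "modularity_score",
    "kl_refine",
    "consensus_partition",
    "partition_similarity",
]


def modularity_score(graph: WeightedGraph, partition: Partition) -> float:
    """Weighted Newman modularity Q in [-1, 1]."""
    if partition.n_nodes != graph.n_nodes:
        raise ValueError(
            f"partition covers {partition.n_nodes} nodes, graph has {graph.n_nodes}"
        )
    w = graph.weights
    total = w.sum() / 2.0
    if total == 0:
        return 0.0
    a = partition.assignment
    q = 0.0
    for mod in range(1, partition.m + 1):
        members = a == mod
        w_m = w[np.ix_(members, members)].sum() / 2.0
        s_m = w[members].sum()
        q += w_m / total - (s_m / (2.0 * total)) ** 2
    return float(q)


def _module_weights(w_row: np.ndarray, assignment: np.ndarray, m: int) -> np.ndarray:
    """Summed weight from one node into each module 1..m."""
    return np.bincount(assignment, weights=w_row, minlength=m + 1)[1:]


def kl_refine(
    graph: WeightedGraph,
    initial: Partition,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Partition:
    """Greedy single-node modularity refinement (Kernighan–Lin style).

    Sweeps nodes in a seeded random order (reshuffled each sweep); each node
    moves to the neighbouring module — or to a new singleton module — with
    the maximal positive gain in Q. Terminates when a full sweep makes no
    move. The result never has lower Q than the initial partition and is
    returned in canonical form.
    """
    if initial.n_nodes != graph.n_nodes:
        raise ValueError("initial partition does not cover the graph")
    if rng is None:
        rng = np.random.default_rng(seed)
    w = graph.weights
    n = graph.n_nodes
    total = w.sum() / 2.0
    if total == 0:
        return Partition(canonicalize_assignment(initial.assignment))
    s = graph.strengths()
    a = initial.assignment.copy()
    a.flags.writeable = True
    m = int(a.max())
    mod_strength = np.bincount(a, weights=s, minlength=m + 2)[: m + 2]

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            cur = a[i]
            k_im = _module_weights(w[i], a, m)
            k_cur = k_im[cur - 1]
            s_i = s[i]
            # gain of moving i from cur into module b (b != cur):
            #   [k_ib - k_icur]/W - s_i (S_b - S_cur + s_i) / (2 W^2)
            gains = (k_im - k_cur) / total - s_i * (
                mod_strength[1 : m + 1] - mod_strength[cur] + s_i
            ) / (2.0 * total**2)
            gains[cur - 1] = 0.0
            # fresh singleton module as an extra candidate
            gain_new = -k_cur / total - s_i * (-mod_strength[cur] + s_i) / (
                2.0 * total**2
            )
            best = int(np.argmax(gains))
            best_gain = gains[best]
            target = best + 1
            if gain_new > best_gain + 1e-15:
                best_gain = gain_new
                target = m + 1
            if best_gain > 1e-12:
                if target == m + 1:
                    m += 1
                    if mod_strength.size < m + 2:
                        mod_strength = np.append(mod_strength, 0.0)
                mod_strength[cur] -= s_i
                mod_strength[target] += s_i
                a[i] = target
                improved = True
        # compact empty module ids so m stays the live module count
        canon = canonicalize_assignment(a)
        a = canon.copy()
        m = int(a.max())
        mod_strength = np.bincount(a, weights=s, minlength=m + 2)[: m + 2]
    return Partition(canonicalize_assignment(a))


def consensus_partition(
    graph: WeightedGraph,
    iterations: int = 100,
    seed: int | None = None,
    mode: str = "modal",
) -> tuple[Partition, list[Partition]]:
    """Chained consensus affiliation over repeated refinements.

    Builds the chain M0 = singletons -> M1 -> ... -> M_iterations where each
    partition seeds the next refinement, every link canonicalized with node
    #1 anchoring module 1. The consensus is either the node-wise modal module
    id over the chain, ties resolved toward the earliest iteration
    (``mode="modal"``), or the refinement of the chain's mean
    co-classification matrix (``mode="coclassification"``).

    Returns (consensus, chain) where chain = [M1, ..., M_iterations].
    """
    if iterations < 1:
        raise ValueError("need at least one refinement iteration")
    if mode not in ("modal", "coclassification"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    chain: list[Partition] = []
    current = Partition.singletons(n)
    for _ in range(iterations):
        current = kl_refine(graph, current, rng=rng)
        chain.append(current)

    if mode == "modal":
        assignments = np.stack([p.assignment for p in chain])  # iters x n
        consensus = np.empty(n, dtype=int)
        for i in range(n):
            vals = assignments[:, i]
            uniq, first_idx, counts = np.unique(
                vals, return_index=True, return_counts=True
            )
            top = counts == counts.max()
            # tie -> value seen at the earliest iteration
            consensus[i] = uniq[top][np.argmin(first_idx[top])]
    else:
        co = np.zeros((n, n))
        for p in chain:
            co += p.assignment[:, None] == p.assignment[None, :]
        co /= len(chain)
        np.fill_diagonal(co, 0.0)
        co_graph = WeightedGraph(graph.node_labels, co)
        consensus = kl_refine(
            co_graph, Partition.singletons(n), rng=rng
        ).assignment
    return Partition(canonicalize_assignment(consensus)), chain


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def partition_similarity(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information 2 I / (H1 + H2) between two partitions.

    Returns 1 for identical partitions (including both single-module); if
    exactly one partition has zero entropy the similarity is 0 by convention.
    """
    if p1.n_nodes != p2.n_nodes:
        raise ValueError("partitions cover different node counts")
    a, b = p1.assignment, p2.assignment
    if np.array_equal(a, b):
        return 1.0
    contingency = np.zeros((p1.m, p2.m))
    np.add.at(contingency, (a - 1, b - 1), 1.0)
    n = a.size
    h1 = _entropy(contingency.sum(axis=1))
    h2 = _entropy(contingency.sum(axis=0))
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    if h1 == 0.0 or h2 == 0.0:
        return 0.0
    pij = contingency / n
    pi = contingency.sum(axis=1) / n
    pj = contingency.sum(axis=0) / n
    outer = pi[:, None] * pj[None, :]
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    return 2.0 * mi / (h1 + h2)
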