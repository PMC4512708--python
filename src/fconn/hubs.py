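"""Hub detection, strength/degree banding, shared-vs-distinct node
comparison between networks, participation coefficients, and
connector/provincial role classification.

A node is a hub when its degree (or strength) lies at least one sample
standard deviation above the network mean. Normalized values are banded into
the four ranges 0.9-1.0, 0.7-0.89, 0.4-0.69 and <0.4; the ">= 0.7" band is
what "top 30%" refers to in this pipeline's reporting.

The participation coefficient of node i under a partition into m modules is

    pc_i = 1 - sum_m (kappa_im / s_i)^2,

kappa_im the connectivity of i into module m (strength-weighted by default,
edge-count mode available). Its maximum in an m-module network is 1 - 1/m;
hubs with pc within 10% of that maximum are connector hubs, hubs below it
provincial hubs.
"""

from __future__ import annotations

import numpy as np

from .graph_core import HubTable, Partition, WeightedGraph
from .metrics import degree_strength

__all__ = [
    "detect_hubs",
    "band_nodes",
    "shared_distinct",
    "participation_coefficient",
    "classify_hub_roles",
    "hub_table",
]

BAND_LABELS = ("0.9-1.0", "0.7-0.89", "0.4-0.69", "<0.4")


def detect_hubs(values: np.ndarray) -> np.ndarray:
    """Hub flags: value >= mean + 1 sample SD (N-1 denominator).

    A constant vector yields no hubs. Flags are invariant under affine
    transforms of the metric vector with positive slope.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 nodes")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.size, dtype=bool)
    return values >= values.mean() + sd


def band_nodes(normalized_values: np.ndarray) -> list[str]:
    """Assign each normalized value in [0, 1] to one of the four bands.

    Band edges are inclusive at the lower boundary: 0.7 falls in 0.7-0.89 and
    0.9 in 0.9-1.0.
    """
    v = np.asarray(normalized_values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("normalized values must lie in [0, 1]")
    out = []
    for x in v:
        if x >= 0.9:
            out.append(BAND_LABELS[0])
        elif x >= 0.7:
            out.append(BAND_LABELS[1])
        elif x >= 0.4:
            out.append(BAND_LABELS[2])
        else:
            out.append(BAND_LABELS[3])
    return out


def shared_distinct(
    network_a: HubTable, network_b: HubTable, threshold: float = 0.7
) -> dict[str, set[str]]:
    """Split nodes into shared / distinct-to-a / distinct-to-b by whether
    their normalized value reaches ``threshold`` in each network."""
    if set(network_a.node_labels) != set(network_b.node_labels):
        raise ValueError("hub tables cover different node universes")
    val_b = dict(zip(network_b.node_labels, network_b.normalized_value))
    shared, only_a, only_b = set(), set(), set()
    for lab, va in zip(network_a.node_labels, network_a.normalized_value):
        vb = val_b[lab]
        if va >= threshold and vb >= threshold:
            shared.add(lab)
        elif va >= threshold:
            only_a.add(lab)
        elif vb >= threshold:
            only_b.add(lab)
    return {"shared": shared, "distinct_a": only_a, "distinct_b": only_b}


def participation_coefficient(
    graph: WeightedGraph, partition: Partition, weighted: bool = True
) -> np.ndarray:
    """pc_i = 1 - sum_m (kappa_im / s_i)^2; 0 for isolated nodes."""
    if partition.n_nodes != graph.n_nodes:
        raise ValueError("partition does not cover the graph")
    w = graph.weights if weighted else (graph.weights > 0).astype(float)
    s = w.sum(axis=1)
    a = partition.assignment
    m = partition.m
    # kappa[i, mod] = connectivity of node i into module mod
    kappa = np.zeros((graph.n_nodes, m))
    for mod in range(1, m + 1):
        kappa[:, mod - 1] = w[:, a == mod].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s[:, None] > 0, kappa / s[:, None], 0.0)
    pc = np.where(s > 0, 1.0 - (frac**2).sum(axis=1), 0.0)
    return np.clip(pc, 0.0, 1.0 - 1.0 / m if m > 1 else 0.0)


def classify_hub_roles(
    hub_flags: np.ndarray, pc: np.ndarray, m: int, margin: float = 0.10
) -> list[str]:
    """Connector/provincial classification of hubs.

    connector: hub with pc_i >= (1 - margin) * (1 - 1/m);
    provincial: hub below that; non-hubs get "none".
    """
    if m < 2:
        raise ValueError("role classification requires m >= 2 modules")
    cutoff = (1.0 - margin) * (1.0 - 1.0 / m)
    roles = []
    for is_hub, p in zip(hub_flags, pc):
        if not is_hub:
            roles.append("none")
        elif p >= cutoff:
            roles.append("connector")
        else:
            roles.append("provincial")
    return roles


def hub_table(
    graph: WeightedGraph,
    metric: str = "strength",
    partition: Partition | None = None,
    weighted_pc: bool = True,
) -> HubTable:
    """Full per-node hub table for one network.

    With a partition, participation coefficients and connector/provincial
    roles are included.
    """
    k, s, k_norm, s_norm = degree_strength(graph)
    if metric == "strength":
        raw, norm = s.astype(float), s_norm
    elif metric == "degree":
        raw, norm = k.astype(float), k_norm
    else:
        raise ValueError("metric must be 'strength' or 'degree'")
    flags = detect_hubs(raw)
    bands = band_nodes(norm)
    pc = roles = m = None
    if partition is not None:
        pc = participation_coefficient(graph, partition, weighted=weighted_pc)
        m = partition.m
        if m >= 2:
            roles = tuple(classify_hub_roles(flags, pc, m))
    return HubTable(
        node_labels=graph.node_labels,
        metric_kind=metric,
        raw_value=raw,
        normalized_value=norm,
        band=tuple(bands),
        is_hub=flags,
        participation=pc,
        role=roles,
        m=m,
    )
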