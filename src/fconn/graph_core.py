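"""Core domain types for weighted functional-connectivity networks.

The pipeline's central object is :class:`WeightedGraph` — a symmetric,
nonnegative, zero-diagonal weight matrix over labelled ROI nodes. Partitions
of the node set are kept in a canonical form in which node #1 belongs to
module 1 and module ids appear in order of first appearance, so that module
labels are comparable across repeated stochastic optimisations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiLabelTable",
    "RoiTimeSeriesPanel",
    "WeightedGraph",
    "DensitySchedule",
    "Partition",
    "MetricReport",
    "HubTable",
    "PermutationResult",
    "canonicalize_assignment",
]

HEMISPHERES = ("L", "R", "midline")
TISSUE_CLASSES = ("cortical", "subcortical", "cerebellar")


class FormatError(ValueError):
    """Malformed input file or matrix shape."""


class LabelError(ValueError):
    """Node labels inconsistent with the ROI label table."""


class SymmetryError(ValueError):
    """Connectivity matrix asymmetric beyond tolerance."""


@dataclass(frozen=True)
class RoiLabelTable:
    """Identity space of the parcellation: one row per region of interest.

    Parameters
    ----------
    table:
        DataFrame with columns ``region_name``, ``hemisphere`` (L/R/midline),
        ``tissue_class`` (cortical/subcortical/cerebellar) and ``atlas_index``
        (unique integers >= 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_name", "hemisphere", "tissue_class", "atlas_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"label table missing columns: {sorted(missing)}")
        names = self.table["region_name"]
        if names.duplicated().any():
            raise LabelError("duplicate region names in label table")
        if self.table["atlas_index"].duplicated().any():
            raise LabelError("duplicate atlas indices in label table")
        if (self.table["atlas_index"] < 1).any():
            raise LabelError("atlas_index must be >= 1")
        bad_hemi = ~self.table["hemisphere"].isin(HEMISPHERES)
        if bad_hemi.any():
            raise LabelError(
                f"unknown hemisphere values: {sorted(self.table.loc[bad_hemi, 'hemisphere'].unique())}"
            )
        bad_tissue = ~self.table["tissue_class"].isin(TISSUE_CLASSES)
        if bad_tissue.any():
            raise LabelError(
                f"unknown tissue classes: {sorted(self.table.loc[bad_tissue, 'tissue_class'].unique())}"
            )

    @property
    def region_names(self) -> list[str]:
        return list(self.table["region_name"])

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, names: Sequence[str]) -> "RoiLabelTable":
        """Restrict the table to ``names``, preserving their given order."""
        index = self.table.set_index("region_name")
        unknown = [n for n in names if n not in index.index]
        if unknown:
            raise LabelError(f"unknown region names: {unknown[:5]}")
        return RoiLabelTable(index.loc[list(names)].reset_index())


@dataclass(frozen=True)
class RoiTimeSeriesPanel:
    """One subject x condition block of ROI time series (T x N)."""

    subject_id: str
    condition: str
    data: np.ndarray
    roi_labels: RoiLabelTable

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise FormatError("time-series panel must be a 2-D T x N array")
        if data.shape[0] < 3:
            raise FormatError("need at least 3 time points")
        if data.shape[1] != len(self.roi_labels):
            raise LabelError(
                f"{data.shape[1]} columns but {len(self.roi_labels)} ROI labels"
            )
        if not np.isfinite(data).all():
            raise FormatError("time series contain missing/non-finite values")
        if np.any(np.std(data, axis=0) == 0):
            const = np.flatnonzero(np.std(data, axis=0) == 0)
            names = [self.roi_labels.region_names[i] for i in const[:5]]
            raise FormatError(f"constant-signal ROI columns rejected: {names}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric nonnegative weighted network over labelled nodes.

    ``weights`` is an N x N matrix with zero diagonal; an entry of 0 means
    "no edge". Construction enforces symmetry (values averaged below a small
    relative tolerance), nonnegativity and the zero diagonal.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    negative_count: int = 0

    def __post_init__(self) -> None:
        labels = tuple(self.node_labels)
        object.__setattr__(self, "node_labels", labels)
        w = np.array(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"weight matrix must be square, got {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise FormatError("graph needs at least 2 nodes")
        if len(labels) != n:
            raise LabelError(f"{len(labels)} labels for {n} nodes")
        if len(set(labels)) != n:
            raise LabelError("duplicate node labels")
        if not np.isfinite(w).all():
            raise FormatError("non-finite weights")
        scale = max(np.abs(w).max(), 1.0)
        if np.abs(w - w.T).max() > 1e-8 * scale:
            raise SymmetryError("weight matrix asymmetric beyond 1e-8 relative")
        w = (w + w.T) / 2.0
        if (w < 0).any():
            raise ValueError("negative weights; clamp at load time")
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, weight) with i < j, lexicographic order."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[i, j]
        keep = w > 0
        return list(zip(i[keep].tolist(), j[keep].tolist(), w[keep].tolist()))

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1).astype(int)

    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def subgraph(self, keep: Sequence[str]) -> "WeightedGraph":
        """Induced subgraph on ``keep`` labels, in the given order."""
        pos = {lab: k for k, lab in enumerate(self.node_labels)}
        unknown = [lab for lab in keep if lab not in pos]
        if unknown:
            raise LabelError(f"unknown node labels: {unknown[:5]}")
        idx = np.array([pos[lab] for lab in keep])
        return WeightedGraph(tuple(keep), self.weights[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DensitySchedule:
    """Strictly increasing list of target connection densities in (0, 1]."""

    densities: tuple[float, ...]

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.densities)
        if not d:
            raise ValueError("empty density schedule")
        if any(not (0.0 < x <= 1.0) for x in d):
            raise ValueError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        object.__setattr__(self, "densities", d)

    @classmethod
    def linear(cls, start: float, stop: float, count: int) -> "DensitySchedule":
        return cls(tuple(np.linspace(start, stop, count)))

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


def canonicalize_assignment(assignment: Sequence[int]) -> np.ndarray:
    """Relabel modules by order of first appearance along the node list.

    Node #1 lands in module 1 and subsequent new modules are numbered
    consecutively, which makes module ids comparable across runs that merely
    permute labels.
    """
    a = np.asarray(assignment, dtype=int)
    mapping: dict[int, int] = {}
    out = np.empty_like(a)
    for k, v in enumerate(a):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[k] = mapping[v]
    return out


@dataclass(frozen=True)
class Partition:
    """Node -> module assignment in canonical form (module ids 1..m)."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1-D vector")
        canon = canonicalize_assignment(a)
        if not np.array_equal(a, canon):
            warnings.warn("non-canonical partition; relabelling modules", stacklevel=2)
            a = canon
        a.flags.writeable = False
        object.__setattr__(self, "assignment", a)

    @property
    def m(self) -> int:
        return int(self.assignment.max())

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    def module_members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)

    @classmethod
    def singletons(cls, n: int) -> "Partition":
        """The artificial all-singleton start M0 = (1, ..., N)."""
        return cls(np.arange(1, n + 1))


@dataclass(frozen=True)
class MetricReport:
    """Per-node and global metrics at one density, with null normalization."""

    node_labels: tuple[str, ...]
    density: float
    degree: np.ndarray
    degree_norm: np.ndarray
    strength: np.ndarray
    strength_norm: np.ndarray
    clustering: np.ndarray
    global_clustering: float
    global_efficiency: float
    clustering_norm: float | None = None
    efficiency_norm: float | None = None
    sigma: float | None = None
    null_count: int | None = None
    null_seed: int | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "global_clustering": self.global_clustering,
            "global_efficiency": self.global_efficiency,
            "clustering_norm": self.clustering_norm,
            "efficiency_norm": self.efficiency_norm,
            "sigma": self.sigma,
            "null_count": self.null_count,
            "null_seed": self.null_seed,
            "notes": list(self.notes),
            "nodes": {
                lab: {
                    "degree": int(self.degree[i]),
                    "degree_norm": float(self.degree_norm[i]),
                    "strength": float(self.strength[i]),
                    "strength_norm": float(self.strength_norm[i]),
                    "clustering": float(self.clustering[i]),
                }
                for i, lab in enumerate(self.node_labels)
            },
        }


@dataclass(frozen=True)
class HubTable:
    """Per-node hub status, strength/degree band, pc and connector role."""

    node_labels: tuple[str, ...]
    metric_kind: str  # "strength" or "degree"
    raw_value: np.ndarray
    normalized_value: np.ndarray
    band: tuple[str, ...]
    is_hub: np.ndarray
    participation: np.ndarray | None = None
    role: tuple[str, ...] | None = None
    m: int | None = None

    def __post_init__(self) -> None:
        if self.metric_kind not in ("strength", "degree"):
            raise ValueError("metric_kind must be 'strength' or 'degree'")
        if self.role is not None:
            if self.m is None or self.m < 2:
                raise ValueError("roles require m >= 2 modules")
            for i, r in enumerate(self.role):
                if r != "none" and not self.is_hub[i]:
                    raise ValueError("connector/provincial role on a non-hub node")
        if self.participation is not None and self.m is not None:
            cap = 1.0 - 1.0 / self.m
            if np.any(self.participation > cap + 1e-12):
                raise ValueError("participation coefficient exceeds 1 - 1/m")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "region": list(self.node_labels),
            "metric": self.metric_kind,
            "value": self.raw_value,
            "normalized": self.normalized_value,
            "band": list(self.band),
            "is_hub": self.is_hub.astype(bool),
        }
        if self.participation is not None:
            data["participation"] = self.participation
        if self.role is not None:
            data["role"] = list(self.role)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class PermutationResult:
    """Paired t statistics with T_max FWE-corrected p values."""

    node_labels: tuple[str, ...]
    t_observed: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    seed: int | None
    exact: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.p_corrected, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("corrected p values must lie in (0, 1]")
        # monotone: larger |t| never gets a larger corrected p
        order = np.argsort(-np.abs(self.t_observed))
        if np.any(np.diff(p[order]) < -1e-12):
            raise ValueError("corrected p not monotone in |t|")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": list(self.node_labels),
                "t": self.t_observed,
                "p_fwe": self.p_corrected,
            }
        )

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [
            lab
            for lab, p in zip(self.node_labels, self.p_corrected)
            if p <= alpha
        ]
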