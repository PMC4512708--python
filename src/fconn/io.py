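"""Readers and writers for connectivity matrices, label tables, partitions.

Canonical on-disk dialects:

* connectivity matrix — delimited text (TSV/CSV) with a header row and header
  column of region names; a headerless square numeric file is accepted when a
  label table supplies the names; MATLAB ``.mat`` containers holding a single
  square matrix are read for compatibility with public deposits;
* label table — TSV with columns region_name, hemisphere, tissue_class,
  atlas_index;
* partition — two-column TSV (node label, module id);
* reports — JSON.

Negative matrix entries are clamped to zero at load and counted (correlation
networks in this pipeline keep only positive couplings); near-symmetric
matrices are symmetrized by averaging, and asymmetry beyond a 1e-8 relative
tolerance is an error.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .graph_core import (
    FormatError,
    LabelError,
    Partition,
    RoiLabelTable,
    SymmetryError,
    WeightedGraph,
    canonicalize_assignment,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_label_table",
    "write_label_table",
    "read_partition",
    "write_partition",
    "write_report",
]


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "," if head.count(",") > head.count("\t") else "\t"


def _from_array(
    raw: np.ndarray, labels: list[str], source: str
) -> WeightedGraph:
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise FormatError(f"{source}: matrix must be square, got {raw.shape}")
    scale = max(np.abs(raw).max(), 1.0)
    asym = np.abs(raw - raw.T).max()
    if asym > 1e-8 * scale:
        raise SymmetryError(
            f"{source}: asymmetric beyond tolerance (max |A - A.T| = {asym:g})"
        )
    w = (raw + raw.T) / 2.0
    np.fill_diagonal(w, 0.0)
    neg = int(np.count_nonzero(np.triu(w, k=1) < 0))
    if neg:
        warnings.warn(
            f"{source}: clamped {neg} negative entries to zero", stacklevel=3
        )
        w = np.clip(w, 0.0, None)
    return WeightedGraph(tuple(labels), w, negative_count=neg)


def read_matrix(
    path: str | Path, labels: RoiLabelTable | None = None
) -> WeightedGraph:
    """Read a square connectivity matrix from delimited text or ``.mat``.

    With a header row + header column the region names come from the file;
    a headerless numeric file requires ``labels``. When both are present the
    file's names must match the label table exactly (case-sensitive).
    """
    path = Path(path)
    if path.suffix.lower() == ".mat":
        contents = scipy.io.loadmat(path)
        arrays = [
            v
            for k, v in contents.items()
            if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
        ]
        if len(arrays) != 1:
            raise FormatError(
                f"{path}: expected exactly one 2-D matrix in MATLAB container, "
                f"found {len(arrays)}"
            )
        raw = np.asarray(arrays[0], dtype=float)
        if labels is None:
            names = [f"node{i + 1}" for i in range(raw.shape[0])]
        else:
            names = labels.region_names
        return _validate_labels(_from_array(raw, names, str(path)), labels)

    sep = _sniff_delimiter(path)
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = not pd.api.types.is_numeric_dtype(first.iloc[0, 1:].infer_objects())
    if has_header:
        df = pd.read_csv(path, sep=sep, index_col=0)
        names = [str(c) for c in df.columns]
        if list(map(str, df.index)) != names:
            raise FormatError(f"{path}: header row and header column disagree")
        raw = df.to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        raw = df.to_numpy(dtype=float)
        if labels is None:
            raise LabelError(f"{path}: headerless matrix requires a label table")
        names = labels.region_names
    graph = _from_array(raw, names, str(path))
    return _validate_labels(graph, labels)


def _validate_labels(
    graph: WeightedGraph, labels: RoiLabelTable | None
) -> WeightedGraph:
    if labels is not None:
        expected = labels.region_names
        if len(expected) != graph.n_nodes:
            raise LabelError(
                f"label table has {len(expected)} rows, matrix {graph.n_nodes}"
            )
        if list(graph.node_labels) != expected:
            raise LabelError("matrix node names do not match the label table")
    return graph


def write_matrix(graph: WeightedGraph, path: str | Path) -> None:
    """Write a graph as TSV with header row + header column."""
    df = pd.DataFrame(
        graph.weights, index=graph.node_labels, columns=graph.node_labels
    )
    df.to_csv(Path(path), sep="\t", float_format="%.10g")


def read_label_table(path: str | Path) -> RoiLabelTable:
    df = pd.read_csv(Path(path), sep="\t")
    return RoiLabelTable(df)


def write_label_table(labels: RoiLabelTable, path: str | Path) -> None:
    labels.table.to_csv(Path(path), sep="\t", index=False)


def write_partition(
    partition: Partition, path: str | Path, node_labels: list[str] | None = None
) -> None:
    """Write a two-column TSV (node label, module id)."""
    if node_labels is None:
        node_labels = [f"node{i + 1}" for i in range(partition.n_nodes)]
    if len(node_labels) != partition.n_nodes:
        raise LabelError("node label count does not match partition size")
    pd.DataFrame(
        {"node": node_labels, "module": partition.assignment}
    ).to_csv(Path(path), sep="\t", index=False)


def read_partition(
    path: str | Path, labels: RoiLabelTable | None = None
) -> tuple[Partition, list[str]]:
    """Read a partition TSV; non-canonical module ids are relabelled.

    Returns the partition and the node labels in file order.
    """
    df = pd.read_csv(Path(path), sep="\t")
    if not {"node", "module"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'node' and 'module'")
    nodes = [str(n) for n in df["node"]]
    if labels is not None:
        known = set(labels.region_names)
        unknown = [n for n in nodes if n not in known]
        if unknown:
            raise LabelError(f"{path}: unknown node labels {unknown[:5]}")
    raw = df["module"].to_numpy(dtype=int)
    canon = canonicalize_assignment(raw)
    if not np.array_equal(raw, canon):
        warnings.warn(f"{path}: partition not canonical; relabelled", stacklevel=2)
    return Partition(canon), nodes


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_timeseries(panel, path: str | Path) -> None:
    """Write a T x N panel as TSV with region-name header columns."""
    pd.DataFrame(panel.data, columns=panel.roi_labels.region_names).to_csv(
        Path(path), sep="\t", index=False, float_format="%.8g"
    )


def read_timeseries(
    path: str | Path,
    labels: RoiLabelTable,
    subject_id: str,
    condition: str,
):
    """Read a T x N panel written by :func:`write_timeseries`.

    The file's column names must match the label table exactly.
    """
    from .graph_core import RoiTimeSeriesPanel

    df = pd.read_csv(Path(path), sep="\t")
    if list(df.columns) != labels.region_names:
        raise LabelError(f"{path}: column names do not match the label table")
    return RoiTimeSeriesPanel(
        subject_id=subject_id,
        condition=condition,
        data=df.to_numpy(dtype=float),
        roi_labels=labels,
    )
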