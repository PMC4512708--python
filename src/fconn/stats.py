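"""Paired and unpaired permutation tests with family-wise error control by
the maximal statistic (T_max).

For a paired comparison of two conditions over nodes, the per-node paired t
statistic is computed on subject differences, and the null distribution is
built by randomly sign-flipping each subject's whole difference vector — the
flip is applied jointly across nodes, which preserves the spatial correlation
the max-statistic correction relies on. The corrected p value of node i is
the fraction of permutations whose maximal |t| across nodes reaches |t_i|.
When the full set of 2^n sign patterns is no larger than the requested
permutation count, the test enumerates them exactly.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from .graph_core import PermutationResult

__all__ = ["paired_permutation_tmax", "group_consistency_check"]


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t statistics column-wise; zero-variance nodes get t = 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    t = np.zeros(diff.shape[1])
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def _t_for_signs(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired t for a batch of sign patterns.

    Sign flips leave each column's sum of squares unchanged, so only the mean
    needs recomputing: var = (SS - n * mean^2) / (n - 1).
    """
    n = diff.shape[0]
    ss = (diff**2).sum(axis=0)  # invariant under sign flips
    mean = signs @ diff / n  # perms x nodes
    var = (ss[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
    return t


def paired_permutation_tmax(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    node_labels: tuple[str, ...] | None = None,
) -> PermutationResult:
    """Two-sided paired permutation test, FWE-corrected via T_max.

    ``values_a`` and ``values_b`` are subjects x nodes matrices of one metric
    under two conditions. Returns per-node t and corrected p in (0, 1].
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n_sub, n_nodes = a.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    diff = a - b
    if np.any(diff.std(axis=0, ddof=1) == 0):
        warnings.warn(
            "zero-variance difference at some nodes; their t set to 0",
            stacklevel=2,
        )
    t_obs = _paired_t(diff)

    exact = 2**n_sub <= n_perm
    if exact:
        signs = np.array(
            list(itertools.product((1.0, -1.0), repeat=n_sub))
        )
        t_perm = _t_for_signs(diff, signs)
        tmax = np.abs(t_perm).max(axis=1)
        # exact: identity pattern included, p = count / 2^n, never 0
        p = (tmax[:, None] >= np.abs(t_obs)[None, :] - 1e-12).mean(axis=0)
        n_used = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        tmax = np.empty(n_perm)
        chunk = max(1, min(n_perm, 200_000_000 // max(n_sub * n_nodes, 1)))
        done = 0
        while done < n_perm:
            take = min(chunk, n_perm - done)
            signs = rng.choice((1.0, -1.0), size=(take, n_sub))
            t_perm = _t_for_signs(diff, signs)
            tmax[done : done + take] = np.abs(t_perm).max(axis=1)
            done += take
        # add-one estimator keeps p > 0
        exceed = (tmax[:, None] >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used = n_perm

    if node_labels is None:
        node_labels = tuple(f"node{i + 1}" for i in range(n_nodes))
    return PermutationResult(
        node_labels=node_labels,
        t_observed=t_obs,
        p_corrected=p,
        n_permutations=n_used,
        seed=seed,
        exact=exact,
    )


def _welch_t(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    na, nb = xa.shape[0], xb.shape[0]
    va = xa.var(axis=0, ddof=1) / na
    vb = xb.var(axis=0, ddof=1) / nb
    denom = np.sqrt(va + vb)
    t = np.zeros(xa.shape[1])
    nz = denom > 0
    t[nz] = (xa.mean(axis=0) - xb.mean(axis=0))[nz] / denom[nz]
    return t


def group_consistency_check(
    series_a: np.ndarray,
    series_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    node_labels: tuple[str, ...] | None = None,
) -> PermutationResult:
    """Unpaired max-statistic permutation test on time-series summaries.

    ``series_a`` and ``series_b`` are subjects x T x nodes arrays from two
    groups. Each subject's series is summarized per node by its mean and SD;
    group labels are permuted and the Welch t statistic of each feature is
    FWE-corrected by the maximum over all features, then collapsed back to
    one corrected p per node (the smaller of the mean/SD feature p values is
    conservative enough for a consistency check).
    """
    sa = np.asarray(series_a, dtype=float)
    sb = np.asarray(series_b, dtype=float)
    if sa.ndim != 3 or sb.ndim != 3 or sa.shape[1:] != sb.shape[1:]:
        raise ValueError("expected subjects x T x nodes arrays over one node set")
    feats_a = np.concatenate([sa.mean(axis=1), sa.std(axis=1, ddof=1)], axis=1)
    feats_b = np.concatenate([sb.mean(axis=1), sb.std(axis=1, ddof=1)], axis=1)
    na, nb = feats_a.shape[0], feats_b.shape[0]
    pooled = np.vstack([feats_a, feats_b])
    t_obs = _welch_t(feats_a, feats_b)

    rng = np.random.default_rng(seed)
    tmax = np.empty(n_perm)
    for p_idx in range(n_perm):
        perm = rng.permutation(na + nb)
        tmax[p_idx] = np.abs(
            _welch_t(pooled[perm[:na]], pooled[perm[na:]])
        ).max()
    exceed = (tmax[:, None] >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    p_feat = (1.0 + exceed) / (n_perm + 1.0)

    n_nodes = sa.shape[2]
    p_node = np.minimum(p_feat[:n_nodes], p_feat[n_nodes:])
    t_node = np.where(
        np.abs(t_obs[:n_nodes]) >= np.abs(t_obs[n_nodes:]),
        t_obs[:n_nodes],
        t_obs[n_nodes:],
    )
    if node_labels is None:
        node_labels = tuple(f"node{i + 1}" for i in range(n_nodes))
    return PermutationResult(
        node_labels=node_labels,
        t_observed=t_node,
        p_corrected=p_node,
        n_permutations=n_perm,
        seed=seed,
    )
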