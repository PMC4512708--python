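"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit triangle enumeration,
Floyd–Warshall, exhaustive set-partition search, direct contingency-table
information — and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela clustering by explicit triangle enumeration."""
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    what = w / wmax
    c = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if w[i, j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        total = 0.0
        for j in neigh:
            for h in neigh:
                if j != h:
                    total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def brute_efficiency(w: np.ndarray) -> float:
    """Global efficiency via Floyd–Warshall on lengths 1/w."""
    n = w.shape[0]
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_modularity(w: np.ndarray, assignment: np.ndarray) -> float:
    """Q = sum_m [W_m/W - (S_m/2W)^2] by explicit module sums."""
    total = w.sum() / 2.0
    if total == 0:
        return 0.0
    q = 0.0
    for mod in np.unique(assignment):
        members = np.flatnonzero(assignment == mod)
        w_m = sum(
            w[i, j] for i in members for j in members if i < j
        )
        s_m = sum(w[i].sum() for i in members)
        q += w_m / total - (s_m / (2 * total)) ** 2
    return q


def brute_nmi(a: np.ndarray, b: np.ndarray) -> float:
    """2 I / (H1 + H2) from the explicit contingency table."""
    n = len(a)
    av, bv = np.unique(a), np.unique(b)
    table = np.array(
        [[np.sum((a == x) & (b == y)) for y in bv] for x in av], dtype=float
    )

    def entropy(counts):
        p = counts / n
        return -sum(pi * math.log(pi) for pi in p if pi > 0)

    h1 = entropy(table.sum(axis=1))
    h2 = entropy(table.sum(axis=0))
    if h1 == 0 and h2 == 0:
        return 1.0
    if h1 == 0 or h2 == 0:
        return 0.0
    mi = 0.0
    for i in range(len(av)):
        for j in range(len(bv)):
            pij = table[i, j] / n
            if pij > 0:
                mi += pij * math.log(
                    pij / ((table[i].sum() / n) * (table[:, j].sum() / n))
                )
    return 2 * mi / (h1 + h2)


def brute_participation(w: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """pc_i = 1 - sum_m (kappa_im / s_i)^2 by explicit per-module sums."""
    n = w.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        s = w[i].sum()
        if s == 0:
            continue
        acc = 0.0
        for mod in np.unique(assignment):
            kappa = w[i, assignment == mod].sum()
            acc += (kappa / s) ** 2
        pc[i] = 1.0 - acc
    return pc


def set_partitions(n: int):
    """All set partitions of range(n) as assignment vectors (1-based ids)."""
    if n == 0:
        return
    codes = [0] * n
    while True:
        yield np.array(codes) + 1
        # next restricted growth string
        i = n - 1
        while i > 0:
            if codes[i] <= max(codes[:i]):
                codes[i] += 1
                for j in range(i + 1, n):
                    codes[j] = 0
                break
            codes[i] = 0
            i -= 1
        else:
            return


def exhaustive_max_modularity(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Best Q over all set partitions of the node set."""
    best_q, best_a = -np.inf, None
    for a in set_partitions(w.shape[0]):
        q = brute_modularity(w, a)
        if q > best_q:
            best_q, best_a = q, a
    return best_q, best_a


def random_graph(
    rng: np.random.Generator, n: int, p_edge: float = 0.6
) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
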