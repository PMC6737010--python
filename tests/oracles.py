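"""Independent brute-force oracles used to cross-check the package.

Everything here is written the slow, obvious way (explicit loops,
Floyd-Warshall, exhaustive enumeration) and never calls the code paths
it verifies.
"""

from __future__ import annotations

import math

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook triple loop.

    ``lengths`` is a symmetric matrix of edge lengths with 0 meaning
    "no edge" off the diagonal.
    """
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _lengths(adj: np.ndarray) -> np.ndarray:
    lengths = np.zeros_like(adj, dtype=float)
    nz = adj > 0
    lengths[nz] = 1.0 / adj[nz]
    return lengths


def global_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(_lengths(adj))
    total, npairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            npairs += 1
            if math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / npairs


def local_efficiency_brute(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency_brute(sub)
    return out


def participation_coefficient_brute(
    adj: np.ndarray, modules: list[int]
) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    mods = sorted(set(modules))
    for i in range(n):
        k = sum(adj[i, j] for j in range(n))
        if k == 0:
            continue
        acc = 0.0
        for s in mods:
            k_is = sum(adj[i, j] for j in range(n) if modules[j] == s)
            acc += (k_is / k) ** 2
        out[i] = 1.0 - acc
    return out


def newman_q_brute(adj: np.ndarray, labels: list[int]) -> float:
    n = adj.shape[0]
    two_m = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for k, subset in enumerate(smaller):
            yield smaller[:k] + [[first] + subset] + smaller[k + 1 :]
        yield [[first]] + smaller


def exhaustive_best_q(adj: np.ndarray) -> float:
    n = adj.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        labels = [0] * n
        for c, block in enumerate(part):
            for node in block:
                labels[node] = c
        best = max(best, newman_q_brute(adj, labels))
    return best


def close_pair_count_brute(xyz: np.ndarray, threshold: float) -> int:
    n = len(xyz)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(xyz[i], xyz[j]) < threshold:
                count += 1
    return count


def anova_f_brute(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F from textbook sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


def pearson_r_brute(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
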