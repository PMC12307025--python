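"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive algorithms (enumeration, Floyd-Warshall,
set-partition search, repeated networkx MSTs) and never call the code
paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def floyd_warshall_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on 1/w edge lengths, naive triple loop."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length(weights: np.ndarray) -> float:
    d = floyd_warshall_distances(weights)
    n = weights.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    if not all(np.isfinite(vals)):
        return float("nan")
    return float(np.mean(vals))


def global_efficiency(weights: np.ndarray) -> float:
    d = floyd_warshall_distances(weights)
    n = weights.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def onnela_clustering(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Triangle enumeration for the Onnela weighted clustering mean."""
    n = weights.shape[0]
    values = np.full(n, np.nan)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    total += (weights[i, j] * weights[i, h]
                              * weights[j, h]) ** (1 / 3)
        values[i] = total / (k * (k - 1))
    defined = ~np.isnan(values)
    mean = float(values[defined].mean()) if defined.any() else float("nan")
    return values, mean


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in _set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def newman_q(weights: np.ndarray, communities: list[list[int]]) -> float:
    two_m = weights.sum()
    s = weights.sum(axis=1)
    q = 0.0
    for comm in communities:
        for i in comm:
            for j in comm:
                q += weights[i, j] - s[i] * s[j] / two_m
    return q / two_m


def exhaustive_modularity(weights: np.ndarray) -> tuple[float, list[list[int]]]:
    """Maximum Newman Q over all set partitions (feasible for n <= 8)."""
    n = weights.shape[0]
    best_q, best_p = -np.inf, None
    for p in _set_partitions(list(range(n))):
        q = newman_q(weights, p)
        if q > best_q:
            best_q, best_p = q, p
    return float(best_q), best_p


def sequential_mst_union(weights: np.ndarray, labels: list[str],
                         m: int) -> list[set[tuple[int, int]]]:
    """Orthogonal MST rounds via repeated networkx Kruskal with removal."""
    w = weights.copy()
    rounds = []
    n = w.shape[0]
    for _ in range(m):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if w[i, j] > 0:
                    g.add_edge(i, j, dist=1.0 / w[i, j],
                               tie=(labels[i], labels[j]))
        if not nx.is_connected(g) or g.number_of_nodes() < n:
            break
        tree = nx.minimum_spanning_tree(g, weight="dist")
        edges = {(min(i, j), max(i, j)) for i, j in tree.edges()}
        rounds.append(edges)
        for i, j in edges:
            w[i, j] = w[j, i] = 0.0
    return rounds


def gce_of_selection(weights: np.ndarray, edges: set[tuple[int, int]]
                     ) -> tuple[float, float, float]:
    """(cost, ge, J) of an edge selection, via the Floyd-Warshall oracle."""
    n = weights.shape[0]
    sel = np.zeros_like(weights)
    for i, j in edges:
        sel[i, j] = sel[j, i] = weights[i, j]
    total = np.triu(weights, 1).sum()
    cost = np.triu(sel, 1).sum() / total
    ge = global_efficiency(sel)
    return float(cost), float(ge), float(ge - cost)


def exhaustive_omst(weights: np.ndarray, labels: list[str]
                    ) -> tuple[int, float]:
    """Best round count and J by evaluating every feasible union.

    Weights are rescaled by their maximum before evaluating J, matching
    the algorithm's definition.
    """
    weights = weights / weights.max()
    n = weights.shape[0]
    rounds = sequential_mst_union(weights, labels, m=(n * (n - 1)) // 2)
    best_m, best_j = 0, -np.inf
    union: set[tuple[int, int]] = set()
    for m, tree in enumerate(rounds, start=1):
        union |= tree
        _, _, j = gce_of_selection(weights, union)
        if j > best_j:
            best_m, best_j = m, j
    return best_m, best_j


def dft_cross_spectrum(x: np.ndarray, y: np.ndarray, fs: float,
                       window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direct O(n^2) DFT cross-spectrum of two windowed signals."""
    n = len(x)
    xs = (x - x.mean()) * window
    ys = (y - y.mean()) * window
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, t) / n)
    fx = basis @ xs
    fy = basis @ ys
    freqs = k * fs / n
    return freqs, fx * np.conj(fy)


def dwpli_direct(imag_parts: np.ndarray) -> float:
    """Direct scalar evaluation of the debiased WPLI formula."""
    s = float(np.sum(imag_parts))
    s2 = float(np.sum(imag_parts ** 2))
    sa = float(np.sum(np.abs(imag_parts)))
    den = sa ** 2 - s2
    if den == 0:
        return 0.0
    return (s ** 2 - s2) / den
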