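"""Weighted segregation and integration metrics with explicit missingness.

Segregation is quantified by the Onnela weighted clustering coefficient
and by Newman modularity (Louvain-optimised); integration by the weighted
characteristic path length; and their balance by the small-world index
sigma = (C/C_null) / (L/L_null) against degree-preserving rewired
surrogates.

Sparse graphs make some metrics undefined.  Missingness is an explicit
state (NaN), never imputed: clustering is missing when no node has two
neighbours, path length is missing on disconnected graphs, and the
small-world index is missing whenever clustering is missing or zero or a
null statistic degenerates.  Every metric is scale invariant because
weights are rescaled to [0, 1] first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .omst import WeightedGraph, shortest_path_matrix

__all__ = [
    "MetricRecord",
    "SmallWorldResult",
    "normalize_weights",
    "clustering_coefficient",
    "modularity",
    "characteristic_path_length",
    "global_efficiency",
    "small_world_index",
    "compute_metrics",
]


@dataclass
class MetricRecord:
    """Per subject x band graph-metric row; NaN marks a missing value."""

    subject_id: str
    band: str
    dwpli_mean: float
    clustering: float
    modularity: float
    path_length: float
    small_world: float
    n_null: int


@dataclass
class SmallWorldResult:
    sigma: float  # NaN when missing
    c_null_mean: float
    l_null_mean: float
    sigma_per_null: np.ndarray
    n_null: int

    @property
    def sigma_sd(self) -> float:
        good = self.sigma_per_null[np.isfinite(self.sigma_per_null)]
        return float(np.std(good, ddof=1)) if good.size > 1 else float("nan")


def normalize_weights(graph: WeightedGraph) -> WeightedGraph:
    """Rescale weights to [0, 1] by dividing by the maximum; zeros persist."""
    mx = graph.weights.max()
    if mx <= 0:
        raise ValueError("cannot normalise an all-zero graph")
    return WeightedGraph(list(graph.labels), graph.weights / mx)


def clustering_coefficient(graph: WeightedGraph
                           ) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering, node values and their mean.

    C_i = (1/(k_i (k_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^(1/3) with
    weights already rescaled to [0, 1].  Nodes with fewer than two
    neighbours have no defined value (NaN) and are excluded from the
    mean; the mean itself is NaN only when *no* node has degree >= 2.
    A triangle-free graph with hubs scores 0, not missing.
    """
    w = graph.weights
    cw = np.cbrt(w)
    numer = np.einsum("ij,jh,hi->i", cw, cw, cw)
    k = (w > 0).sum(axis=1).astype(float)
    defined = k >= 2
    values = np.full(graph.n_nodes, np.nan)
    denom = k * (k - 1)
    values[defined] = numer[defined] / denom[defined]
    mean = float(values[defined].mean()) if defined.any() else float("nan")
    return values, mean


def _to_networkx(graph: WeightedGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for i, j in graph.edges():
        g.add_edge(i, j, weight=float(graph.weights[i, j]))
    return g


def _partition_q(graph: WeightedGraph, communities: list[set[int]]) -> float:
    """Weighted Newman modularity of a partition."""
    w = graph.weights
    two_m = w.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an all-zero graph")
    s = w.sum(axis=1)
    q = 0.0
    for comm in communities:
        idx = np.fromiter(comm, dtype=int)
        q += w[np.ix_(idx, idx)].sum() - s[idx].sum() ** 2 / two_m
    return float(q / two_m)


def _exact_modularity(graph: WeightedGraph
                      ) -> tuple[float, list[set[int]]]:
    """Globally optimal Q by enumerating all set partitions.

    Partitions are generated as restricted growth strings; feasible for
    the small graphs (n <= 8) where Louvain's greedy moves can stall in
    a local optimum.
    """
    n = graph.n_nodes
    best_q, best = -np.inf, None
    a = [0] * n
    b = [1] * n  # b[i] = 1 + max(a[:i])
    while True:
        k = max(a) + 1
        comms = [set() for _ in range(k)]
        for i, c in enumerate(a):
            comms[c].add(i)
        q = _partition_q(graph, comms)
        if q > best_q:
            best_q, best = q, comms
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i]:
            i -= 1
        if i == 0:
            break
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = max(b[i], a[i] + 1) if j == i + 1 else \
                max(b[j - 1], a[j - 1] + 1)
    return best_q, best


def modularity(graph: WeightedGraph, restarts: int = 20, seed: int = 0,
               exact_max_nodes: int = 8) -> tuple[float, dict[str, int]]:
    """Maximum-modularity partition and its Q.

    Graphs with at most ``exact_max_nodes`` nodes are solved exactly by
    partition enumeration; larger graphs run Louvain ``restarts`` times
    with seeds derived from ``seed`` and keep the highest-Q partition.
    The trivial one-community partition (Q = 0) is always a candidate,
    so the result is never negative on a connected graph by optimiser
    accident.
    """
    if graph.weights.sum() == 0:
        raise ValueError("modularity undefined on an all-zero graph")
    if graph.n_nodes <= exact_max_nodes:
        best_q, comms = _exact_modularity(graph)
        partition = {graph.labels[i]: c
                     for c, comm in enumerate(comms) for i in comm}
        return best_q, partition
    g = _to_networkx(graph)
    best: list[set[int]] = [set(range(graph.n_nodes))]
    best_q = _partition_q(graph, best)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2 ** 31 - 1)))
        comms = [set(c) for c in comms]
        q = _partition_q(graph, comms)
        if q > best_q:
            best_q, best = q, comms
    partition = {
        graph.labels[i]: c for c, comm in enumerate(best) for i in comm
    }
    return best_q, partition


def characteristic_path_length(graph: WeightedGraph) -> float:
    """Mean weighted shortest-path distance over ordered node pairs.

    Edge lengths are 1/w on the (normalised) weights.  Returns NaN when
    the graph is disconnected — the estimand is undefined rather than
    silently replaced by an efficiency-style harmonic mean.
    """
    n = graph.n_nodes
    if n < 2:
        return float("nan")
    d = shortest_path_matrix(graph.weights)
    off = ~np.eye(n, dtype=bool)
    if not np.all(np.isfinite(d[off])):
        return float("nan")
    return float(d[off].mean())


def global_efficiency(graph: WeightedGraph) -> float:
    """Mean inverse weighted shortest-path distance (1/inf = 0)."""
    n = graph.n_nodes
    if n < 2:
        return float("nan")
    d = shortest_path_matrix(graph.weights)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def _rewired_surrogate(graph: WeightedGraph, rng: np.random.Generator
                       ) -> WeightedGraph:
    """Degree-preserving rewired null with weights shuffled among edges.

    Connected double-edge swaps keep the surrogate spanning-connected so
    its path length stays defined; weights are then permuted uniformly
    over the new edge set.
    """
    g = _to_networkx(graph)
    n_edges = g.number_of_edges()
    nswap = max(1, 10 * n_edges)
    try:
        nx.connected_double_edge_swap(
            g, nswap=nswap, seed=int(rng.integers(2 ** 31 - 1)))
    except nx.NetworkXError:
        pass  # too few swappable pairs; weight shuffle still randomises
    wlist = np.sort(graph.weights[np.triu_indices(graph.n_nodes, k=1)])
    wlist = wlist[wlist > 0]
    rng.shuffle(wlist)
    weights = np.zeros_like(graph.weights)
    for (i, j), w in zip(g.edges(), wlist):
        weights[i, j] = w
        weights[j, i] = w
    return WeightedGraph(list(graph.labels), weights)


def small_world_index(graph: WeightedGraph, n_null: int = 50, seed: int = 0
                      ) -> SmallWorldResult:
    """sigma = (C/C_null) / (L/L_null) against rewired surrogates.

    Missing (NaN) when the graph's own clustering is missing or zero,
    its path length is missing, or the surrogate means degenerate —
    which is what happens on trees and other very sparse graphs.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    _, c = clustering_coefficient(graph)
    length = characteristic_path_length(graph)
    nan = float("nan")
    if not math.isfinite(c) or c == 0 or not math.isfinite(length):
        return SmallWorldResult(nan, nan, nan, np.full(n_null, np.nan),
                                n_null)
    rng = np.random.default_rng(seed)
    c_nulls = np.empty(n_null)
    l_nulls = np.empty(n_null)
    for k in range(n_null):
        surr = _rewired_surrogate(graph, rng)
        _, c_nulls[k] = clustering_coefficient(surr)
        l_nulls[k] = characteristic_path_length(surr)
    c_bar = float(np.nanmean(c_nulls))
    l_bar = float(np.nanmean(l_nulls))
    if not (math.isfinite(c_bar) and math.isfinite(l_bar)) \
            or c_bar == 0 or l_bar == 0:
        return SmallWorldResult(nan, c_bar, l_bar, np.full(n_null, np.nan),
                                n_null)
    sigma = (c / c_bar) / (length / l_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_null = (c / c_nulls) / (length / l_nulls)
    return SmallWorldResult(float(sigma), c_bar, l_bar, per_null, n_null)


def compute_metrics(subject_id: str, band: str, dwpli_mean: float,
                    graph: WeightedGraph, n_null: int = 50,
                    restarts: int = 20, seed: int = 0) -> MetricRecord:
    """All graph metrics for one normalised subject x band graph."""
    norm = normalize_weights(graph)
    _, clust = clustering_coefficient(norm)
    q, _ = modularity(norm, restarts=restarts, seed=seed)
    length = characteristic_path_length(norm)
    sw = small_world_index(norm, n_null=n_null, seed=seed)
    return MetricRecord(subject_id, band, dwpli_mean, clust, q, length,
                        sw.sigma, n_null)
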