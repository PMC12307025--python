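"""Orthogonalized-minimum-spanning-tree (OMST) thresholding.

Dense association matrices such as dwPLI weight every channel pair, most
weakly; thresholding is needed before graph metrics, but any fixed density
is arbitrary.  The OMST scheme is data driven: it extracts successive
edge-disjoint maximum-weight spanning trees (minimum trees under the
distance 1/w) and keeps the union of the first m* trees, where m*
maximises the global cost efficiency J = GE - Cost.  GE is the mean
inverse shortest-path distance over ordered node pairs of the selected
graph and Cost is the selected fraction of total weight, so J rewards
efficient shortcuts while penalising wiring.

The resulting graph always contains the first spanning tree, hence is
connected and spans all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "WeightedGraph",
    "OMSTSelection",
    "max_weight_mst",
    "orthogonal_msts",
    "global_cost_efficiency",
    "select_omst",
    "shortest_path_matrix",
]

Edge = tuple[int, int]


@dataclass
class WeightedGraph:
    """Undirected weighted graph on labelled nodes.

    ``weights`` is a symmetric nonnegative matrix with zero diagonal; an
    entry of 0 means "no edge".  The distance of an edge is 1/w, so
    stronger connections are shorter.
    """

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape must match label count")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def edges(self) -> list[Edge]:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def distance_matrix(self) -> np.ndarray:
        """Edge lengths 1/w; absent edges are +inf."""
        with np.errstate(divide="ignore"):
            d = np.where(self.weights > 0, 1.0 / self.weights, np.inf)
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class OMSTSelection:
    """Result of OMST thresholding."""

    mst_rounds: list[frozenset[Edge]]
    m_star: int
    gce_curve: list[tuple[int, float, float, float]]  # (m, cost, ge, J)
    thresholded: WeightedGraph
    selected_edges: frozenset[Edge] = field(default_factory=frozenset)


def shortest_path_matrix(weights: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances with edge lengths 1/w."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return shortest_path(lengths, method="D", directed=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _components(weights: np.ndarray) -> list[list[int]]:
    n_comp, assignment = connected_components(weights > 0, directed=False)
    return [np.flatnonzero(assignment == c).tolist() for c in range(n_comp)]


def max_weight_mst(graph: WeightedGraph) -> frozenset[Edge]:
    """Spanning tree keeping the strongest edges (minimum total 1/w).

    Kruskal's algorithm; equal-weight edges are broken lexicographically
    by label pair so results are reproducible across platforms.
    """
    n = graph.n_nodes
    comps = _components(graph.weights)
    if len(comps) > 1:
        names = [[graph.labels[i] for i in c] for c in comps]
        raise ValueError(f"graph is disconnected; components: {names}")
    cand = sorted(
        graph.edges(),
        key=lambda e: (-graph.weights[e], graph.labels[e[0]],
                       graph.labels[e[1]]),
    )
    uf = _UnionFind(n)
    tree: set[Edge] = set()
    for i, j in cand:
        if uf.union(i, j):
            tree.add((i, j))
            if len(tree) == n - 1:
                break
    return frozenset(tree)


def orthogonal_msts(graph: WeightedGraph, m: int) -> list[frozenset[Edge]]:
    """Up to ``m`` edge-disjoint spanning trees, strongest first.

    Round r computes an MST on the graph with rounds 1..r-1 removed;
    extraction stops early when the residual graph no longer spans all
    nodes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    residual = WeightedGraph(list(graph.labels), graph.weights.copy())
    rounds: list[frozenset[Edge]] = []
    for _ in range(m):
        if len(_components(residual.weights)) > 1:
            break
        tree = max_weight_mst(residual)
        rounds.append(tree)
        for i, j in tree:
            residual.weights[i, j] = 0.0
            residual.weights[j, i] = 0.0
    if not rounds:
        raise ValueError("graph is disconnected; no spanning tree exists")
    return rounds


def _selection_weights(edges: frozenset[Edge],
                       original: WeightedGraph) -> np.ndarray:
    sel = np.zeros_like(original.weights)
    for i, j in edges:
        sel[i, j] = original.weights[i, j]
        sel[j, i] = original.weights[j, i]
    return sel


def global_cost_efficiency(edges: frozenset[Edge], original: WeightedGraph
                           ) -> tuple[float, float, float]:
    """(cost, global efficiency, J) of an edge selection.

    cost = selected weight / total weight; GE = mean over ordered node
    pairs of 1/d with d the weighted shortest-path distance on the
    selected graph (1/inf = 0); J = GE - cost.
    """
    total = float(np.triu(original.weights, k=1).sum())
    if total == 0:
        raise ValueError("graph has no edges")
    sel = _selection_weights(edges, original)
    cost = float(np.triu(sel, k=1).sum()) / total
    n = original.n_nodes
    if n < 2 or not edges:
        return cost, 0.0, 0.0 - cost
    d = shortest_path_matrix(sel)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    ge = float(inv.sum()) / (n * (n - 1))
    return cost, ge, ge - cost


def select_omst(graph: WeightedGraph, max_rounds: int | None = None,
                exhaustive: bool = False, patience: int = 3
                ) -> OMSTSelection:
    """OMST thresholding: keep the union of trees maximising J = GE - Cost.

    Weights are first rescaled to [0, 1] by their maximum, as in the
    published algorithm, so global efficiency and cost live on the same
    scale (the MST rounds and the cost ratio are scale invariant; GE is
    not).  J is evaluated on the cumulative union after each round.  By
    default up to ``floor((n-1)/2)`` rounds are considered and the scan
    stops after ``patience`` consecutive decreases of J (the curve is
    close to concave in practice); ``exhaustive=True`` disables the early
    stop.  Ties in J resolve to the smaller round count.  The returned
    thresholded graph keeps the *original* weights on the selected edges.
    """
    n = graph.n_nodes
    mx = graph.weights.max()
    if mx <= 0:
        raise ValueError("graph has no edges")
    scaled = WeightedGraph(list(graph.labels), graph.weights / mx)
    if max_rounds is None:
        max_rounds = max(1, (n - 1) // 2)
    rounds = orthogonal_msts(graph, max_rounds)
    if exhaustive:
        patience = len(rounds) + 1
    curve: list[tuple[int, float, float, float]] = []
    union: set[Edge] = set()
    best_j = -np.inf
    decreases = 0
    prev_j = -np.inf
    for m, tree in enumerate(rounds, start=1):
        union |= tree
        cost, ge, j = global_cost_efficiency(frozenset(union), scaled)
        curve.append((m, cost, ge, j))
        if j < prev_j:
            decreases += 1
        else:
            decreases = 0
        prev_j = j
        best_j = max(best_j, j)
        if decreases >= patience:
            break
    m_star = 1 + int(np.argmax([c[3] for c in curve]))
    selected: set[Edge] = set()
    for tree in rounds[:m_star]:
        selected |= tree
    thresholded = WeightedGraph(list(graph.labels),
                                _selection_weights(frozenset(selected), graph))
    return OMSTSelection(rounds[: len(curve)], m_star, curve, thresholded,
                         frozenset(selected))
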