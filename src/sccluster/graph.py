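"""Pairwise-correlation similarity and the iterative k-MST graph.

The k-MST graph is the union of k edge-disjoint spanning trees computed
iteratively: each round runs Kruskal's algorithm on the complete distance
graph minus the edges already selected, so later trees draw from a strictly
depleted (and therefore no cheaper) edge set. Compared with a k-NN graph the
union is denser but still guarantees every node at least degree k while the
residual graphs stay connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConstantRowError

__all__ = [
    "SimilarityMatrix",
    "WeightedGraph",
    "KMSTConfig",
    "pearson_similarity",
    "similarity_to_distance",
    "default_k",
    "build_kmst",
]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n Pearson correlations between cell expression vectors."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightedGraph:
    """Edge-weighted undirected graph over nodes 0..n-1.

    Edges are stored once with i < j; no self-loops, no duplicates.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        canon = []
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight on edge ({i}, {j})")
            seen.add((i, j))
            canon.append((int(i), int(j), float(w)))
        self.edges = canon

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges)

    def degrees(self) -> np.ndarray:
        """Unweighted degree per node."""
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def weighted_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=float)
        for i, j, w in self.edges:
            deg[i] += w
            deg[j] += w
        return deg


@dataclass
class KMSTConfig:
    """Settings for the k-MST + Louvain clustering stage.

    ``k='auto'`` uses ceil(ln n) spanning-tree iterations, the count under
    which every node keeps degree >= k while residual graphs stay connected.
    """

    k: int | str = "auto"
    seed: int = 0
    louvain_resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.k != "auto":
            self.k = int(self.k)
            if self.k < 1:
                raise ValueError("k must be >= 1 (or 'auto')")
        if self.louvain_resolution <= 0:
            raise ValueError("louvain_resolution must be positive")

    def resolve_k(self, n: int) -> int:
        return default_k(n) if self.k == "auto" else int(self.k)


def pearson_similarity(matrix: np.ndarray) -> SimilarityMatrix:
    """Pearson correlation between every pair of cell (row) vectors.

    c_ij = cov(x_i, x_j) / (sigma_i * sigma_j); the diagonal is exactly 1
    and zero-variance cells raise :class:`ConstantRowError` naming the cell.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 cells")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        idx = int(np.argmin(sd))
        raise ConstantRowError(
            f"cell {idx} has zero variance; correlation undefined"
        )
    c = np.corrcoef(x)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return SimilarityMatrix(c)


def similarity_to_distance(s: SimilarityMatrix) -> np.ndarray:
    """Map correlations to MST costs: d_ij = 1 - c_ij (range [0, 2], diag 0)."""
    d = 1.0 - s.values
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def default_k(n: int) -> int:
    """Number of spanning-tree iterations: max(1, ceil(ln n))."""
    if n < 2:
        raise ValueError("need at least 2 cells")
    return max(1, math.ceil(math.log(n)))


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def build_kmst(
    d: np.ndarray, k: int
) -> tuple[WeightedGraph, list[set[tuple[int, int]]]]:
    """Union of k edge-disjoint minimum spanning trees of the distance matrix.

    Each iteration runs Kruskal's algorithm over the edges not yet selected,
    with ties broken by (weight, i, j) for determinism. If removing earlier
    trees disconnects the residual graph, the iteration yields the minimum
    spanning forest of what remains (degree guarantees then degrade
    gracefully). Edge weights on the returned union carry the similarity
    1 - d_ij for downstream community detection.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be finite")

    iu, ju = np.triu_indices(n, k=1)
    w = d[iu, ju]
    order = np.lexsort((ju, iu, w))  # (weight, i, j) ascending
    iu, ju = iu[order], ju[order]

    available = np.ones(iu.shape[0], dtype=bool)
    trees: list[set[tuple[int, int]]] = []
    union_edges: list[tuple[int, int, float]] = []
    for _ in range(k):
        uf = _UnionFind(n)
        tree: set[tuple[int, int]] = set()
        for e in np.flatnonzero(available):
            a, b = int(iu[e]), int(ju[e])
            if uf.union(a, b):
                tree.add((a, b))
                available[e] = False
                union_edges.append((a, b, 1.0 - d[a, b]))
                if len(tree) == n - 1:
                    break
        trees.append(tree)
    return WeightedGraph(n, union_edges), trees
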