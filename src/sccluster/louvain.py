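"""Modularity and a seeded Louvain community-detection implementation.

Modularity is evaluated in its directed form — both ordered directions of
every undirected edge contribute and T sums over ordered pairs — which on an
undirected graph reduces to the familiar Newman formula with w_out = w_in =
weighted degree. Louvain proceeds by the standard two phases (greedy local
node moves, then community aggregation) repeated until modularity stops
improving; node visitation order is shuffled by the seed, making runs
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import WeightedGraph

__all__ = ["Partition", "modularity", "louvain"]


@dataclass
class Partition:
    """Community labels per node, 0-based and contiguous."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        uniq = np.unique(lab)
        if lab.size and not np.array_equal(uniq, np.arange(uniq.size)):
            # relabel to 0..K-1 by first appearance for a canonical form
            remap = {}
            out = np.empty_like(lab)
            for idx, v in enumerate(lab):
                if v not in remap:
                    remap[v] = len(remap)
                out[idx] = remap[v]
            lab = out
        self.labels = lab

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def modularity(g: WeightedGraph, p: Partition) -> float:
    """M(G, C) = sum over ordered same-community pairs of e_ij/T - w_out(i) w_in(j)/T^2.

    Each undirected edge is materialized in both directions, so T is twice
    the total edge weight and w_out = w_in = weighted degree. The i = j terms
    (e_ii = 0) contribute their null-model penalty, so a singleton partition
    has strictly negative modularity on any graph with edges.
    """
    labels = np.asarray(p.labels)
    if labels.shape[0] != g.n_nodes:
        raise ValueError("partition does not cover all nodes")
    total = g.total_weight()
    if total <= 0:
        return 0.0
    t = 2.0 * total
    deg = g.weighted_degrees()
    n_comm = int(labels.max()) + 1
    w_in = np.zeros(n_comm)  # undirected within-community weight
    for i, j, w in g.edges:
        if labels[i] == labels[j]:
            w_in[labels[i]] += w
    deg_sum = np.zeros(n_comm)
    np.add.at(deg_sum, labels, deg)
    return float(np.sum(2.0 * w_in / t - (deg_sum / t) ** 2))


def _local_moves(
    adj: list[dict[int, float]],
    deg: np.ndarray,
    t: float,
    resolution: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Phase 1: greedily move nodes between communities until no gain."""
    n = len(adj)
    labels = np.arange(n)
    comm_tot = deg.copy()  # sum of weighted degrees per community
    improved_any = False
    while True:
        moved = False
        for i in rng.permutation(n):
            ci = labels[i]
            # weight from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[labels[j]] = links.get(labels[j], 0.0) + w
            comm_tot[ci] -= deg[i]
            base = links.get(ci, 0.0) - resolution * deg[i] * comm_tot[ci] / t
            best_comm, best_gain = ci, 0.0
            for c, w_ic in sorted(links.items()):
                if c == ci:
                    continue
                gain = (w_ic - resolution * deg[i] * comm_tot[c] / t) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_comm = gain, c
            comm_tot[best_comm] += deg[i]
            if best_comm != ci:
                labels[i] = best_comm
                moved = True
                improved_any = True
        if not moved:
            break
    return labels, improved_any


def _aggregate(
    adj: list[dict[int, float]],
    self_w: np.ndarray,
    labels: np.ndarray,
) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    """Phase 2: collapse communities into super-nodes."""
    uniq, compact = np.unique(labels, return_inverse=True)
    k = uniq.size
    new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
    new_self = np.zeros(k)
    for c in range(k):
        members = np.flatnonzero(compact == c)
        new_self[c] += float(self_w[members].sum())
    for i, nbrs in enumerate(adj):
        ci = compact[i]
        for j, w in nbrs.items():
            if j <= i:
                continue
            cj = compact[j]
            if ci == cj:
                new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_self, compact


def louvain(g: WeightedGraph, seed: int = 0, resolution: float = 1.0) -> Partition:
    """Two-phase Louvain modularity optimization on a weighted graph.

    Starts from singleton communities, greedily relocates nodes to the
    neighboring community with the largest modularity gain, aggregates, and
    repeats. Deterministic for a fixed seed; the returned partition's
    modularity is never below the singleton partition's.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot cluster an empty graph")
    rng = np.random.default_rng(seed)

    adj: list[dict[int, float]] = [dict() for _ in range(g.n_nodes)]
    for i, j, w in g.edges:
        if w <= 0:
            continue  # nonpositive weights carry no community signal
        adj[i][j] = adj[i].get(j, 0.0) + w
        adj[j][i] = adj[j].get(i, 0.0) + w
    self_w = np.zeros(g.n_nodes)

    total = sum(w for _, _, w in g.edges if w > 0)
    node_map = np.arange(g.n_nodes)  # original node -> current super-node
    if total <= 0:
        return Partition(np.zeros(g.n_nodes, dtype=int))
    t = 2.0 * total

    while True:
        deg = np.array(
            [sum(nbrs.values()) + 2.0 * sw for nbrs, sw in zip(adj, self_w)]
        )
        labels, improved = _local_moves(adj, deg, t, resolution, rng)
        if not improved:
            break
        adj, self_w, compact = _aggregate(adj, self_w, labels)
        node_map = compact[node_map]  # compact maps old super-node -> new
        if len(adj) == 1:
            break
    return Partition(node_map)
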