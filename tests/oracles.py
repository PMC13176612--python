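"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation without log-space tricks — and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# spanning trees


def all_spanning_trees(n: int, dist: np.ndarray):
    """Every spanning tree of the complete graph K_n as a frozenset of edges."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    trees = []
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(frozenset(subset))
    return trees


def min_spanning_tree_weight(n: int, dist: np.ndarray) -> float:
    return min(sum(dist[a, b] for a, b in t) for t in all_spanning_trees(n, dist))


# ---------------------------------------------------------------------------
# partitions and modularity


def all_partitions(items):
    """Every set partition of *items* (list of lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in all_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def partition_to_labels(parts, n: int) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    for c, block in enumerate(parts):
        for node in block:
            labels[node] = c
    return labels


def modularity_bruteforce(n: int, edges, labels) -> float:
    """Directed-form modularity: sum over ordered same-community pairs."""
    w = np.zeros((n, n))
    for i, j, wt in edges:
        w[i, j] += wt
        w[j, i] += wt
    t = w.sum()
    if t == 0:
        return 0.0
    wout = w.sum(axis=1)
    win = w.sum(axis=0)
    m = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                m += w[i, j] / t - wout[i] * win[j] / (t * t)
    return m


def best_partition_modularity(n: int, edges) -> float:
    """Maximum modularity over every partition of the node set."""
    best = -np.inf
    for parts in all_partitions(range(n)):
        labels = partition_to_labels(parts, n)
        best = max(best, modularity_bruteforce(n, edges, labels))
    return best


# ---------------------------------------------------------------------------
# likelihoods


def zinb_pmf_direct(k: int, pi: float, mu: float, theta: float) -> float:
    """ZINB pmf from the textbook formula, no log-space evaluation."""
    nb = (
        math.gamma(k + theta)
        / (math.gamma(theta) * math.factorial(k))
        * (theta / (theta + mu)) ** theta
        * (mu / (theta + mu)) ** k
    )
    if k == 0:
        return pi + (1.0 - pi) * nb
    return (1.0 - pi) * nb


def zinb_loss_direct(x, pi, mu, theta) -> float:
    x = np.atleast_2d(x)
    pi, mu, theta = np.atleast_2d(pi), np.atleast_2d(mu), np.atleast_2d(theta)
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total -= math.log(zinb_pmf_direct(int(x[i, j]), pi[i, j], mu[i, j], theta[i, j]))
    return total


def gmm_nll_direct(x, weights, means, variances) -> float:
    """Mixture NLL by direct density summation (diagonal covariances)."""
    x = np.atleast_2d(x)
    d = means.shape[1]
    total = 0.0
    for xi in x:
        p = 0.0
        for wc, mc, vc in zip(weights, means, variances):
            norm = (2.0 * math.pi) ** (-d / 2.0) * np.prod(vc) ** -0.5
            p += wc * norm * math.exp(-0.5 * float(np.sum((xi - mc) ** 2 / vc)))
        total -= math.log(p)
    return total


# ---------------------------------------------------------------------------
# clustering metrics


def accuracy_bruteforce(truth, pred) -> float:
    """Best accuracy over every injective map between label sets."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    t_vals = sorted(set(truth.tolist()))
    p_vals = sorted(set(pred.tolist()))
    # map the smaller side injectively into the larger
    best = 0
    if len(p_vals) <= len(t_vals):
        for perm in itertools.permutations(t_vals, len(p_vals)):
            mapping = dict(zip(p_vals, perm))
            best = max(best, sum(mapping[p] == t for p, t in zip(pred, truth)))
    else:
        for perm in itertools.permutations(p_vals, len(t_vals)):
            mapping = dict(zip(t_vals, perm))
            best = max(best, sum(mapping[t] == p for p, t in zip(pred, truth)))
    return best / truth.shape[0]


def nmi_bruteforce(truth, pred) -> float:
    """MI / arithmetic mean of entropies, from the contingency counts."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = truth.shape[0]
    t_vals, p_vals = sorted(set(truth.tolist())), sorted(set(pred.tolist()))
    mi = 0.0
    for tv in t_vals:
        for pv in p_vals:
            nij = np.sum((truth == tv) & (pred == pv))
            if nij == 0:
                continue
            ni = np.sum(truth == tv)
            nj = np.sum(pred == pv)
            mi += (nij / n) * math.log(n * nij / (ni * nj))
    ht = -sum(
        (np.sum(truth == tv) / n) * math.log(np.sum(truth == tv) / n) for tv in t_vals
    )
    hp = -sum(
        (np.sum(pred == pv) / n) * math.log(np.sum(pred == pv) / n) for pv in p_vals
    )
    denom = 0.5 * (ht + hp)
    if denom == 0:
        return 1.0 if ht == hp == 0 else 0.0
    return max(0.0, mi / denom)


def ari_bruteforce(truth, pred) -> float:
    """(RI - E[RI]) / (max RI - E[RI]) from pair counts."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = truth.shape[0]

    def comb2(x):
        return x * (x - 1) / 2.0

    t_vals, p_vals = sorted(set(truth.tolist())), sorted(set(pred.tolist()))
    sum_ij = sum(
        comb2(np.sum((truth == tv) & (pred == pv)))
        for tv in t_vals
        for pv in p_vals
    )
    sum_i = sum(comb2(np.sum(truth == tv)) for tv in t_vals)
    sum_j = sum(comb2(np.sum(pred == pv)) for pv in p_vals)
    expected = sum_i * sum_j / comb2(n)
    maximum = 0.5 * (sum_i + sum_j)
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)
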