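"""Independent brute-force oracles used by the test-suite.

These deliberately re-derive results through different code paths than the
package (exhaustive enumeration, direct formulas, networkx path matrices) so
that agreement is informative.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def fisher_two_tailed_enumeration(table) -> float:
    """Two-tailed Fisher exact p by exhaustive hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    return sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs * (1 + 1e-9))


def _unrooted_topologies(n: int):
    """All unrooted binary topologies over leaves 0..n-1 as networkx graphs."""
    g = nx.Graph()
    g.add_edges_from([(0, n), (1, n), (2, n)])
    trees = [g]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for t in trees:
            for u, v in list(t.edges):
                t2 = t.copy()
                t2.remove_edge(u, v)
                w = next_internal
                t2.add_edges_from([(u, w), (v, w), (w, leaf)])
                new_trees.append(t2)
        trees = new_trees
        next_internal += 1
    return trees


def ols_me_minimum_length(d: np.ndarray) -> float:
    """Minimal total OLS branch length over all topologies (exhaustive)."""
    n = d.shape[0]
    best = np.inf
    pairs = list(itertools.combinations(range(n), 2))
    for t in _unrooted_topologies(n):
        edges = list(t.edges)
        eidx = {frozenset(e): i for i, e in enumerate(edges)}
        A = np.zeros((len(pairs), len(edges)))
        y = np.empty(len(pairs))
        for r, (i, j) in enumerate(pairs):
            path = nx.shortest_path(t, i, j)
            for u, v in zip(path, path[1:]):
                A[r, eidx[frozenset((u, v))]] = 1.0
            y[r] = d[i, j]
        lengths, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        total = float(lengths.sum())
        if total < best:
            best = total
    return best


def chi_square_direct(table: np.ndarray) -> float:
    """Pearson chi-square statistic by the direct sum over cells."""
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat
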