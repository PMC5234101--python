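"""Minimal-evolution phylogenetic trees from sample distance matrices.

The minimal-evolution (ME) criterion picks the unrooted binary topology
whose total branch length — estimated by ordinary least squares (OLS) on
the pairwise distances — is smallest. Per-patient phyloepigenetic trees
have few leaves (averaged normals, a handful of foci, one or two
metastases), so topologies are enumerated exhaustively up to
``EXHAUSTIVE_MAX_LEAVES`` leaves; larger inputs start from a
neighbor-joining tree and hill-climb with nearest-neighbor interchanges.

Negative OLS branch-length estimates are truncated to zero for display
(count recorded); the search objective is the raw OLS length sum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

log = logging.getLogger(__name__)

EXHAUSTIVE_MAX_LEAVES = 8

Adjacency = dict[int, list[int]]


# ---------------------------------------------------------------------------
# topology plumbing (leaves are 0..n-1; internal nodes >= n)


def _edges(adj: Adjacency) -> list[tuple[int, int]]:
    return sorted({(min(u, v), max(u, v)) for u in adj for v in adj[u]})


def _leaf_path(adj: Adjacency, a: int, b: int) -> list[tuple[int, int]]:
    """Edge list of the unique path between nodes a and b."""
    parent = {a: a}
    stack = [a]
    while stack:
        u = stack.pop()
        if u == b:
            break
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    path = []
    u = b
    while u != a:
        p = parent[u]
        path.append((min(u, p), max(u, p)))
        u = p
    return path


def ols_branch_lengths(adj: Adjacency, d: np.ndarray, n_leaves: int):
    """OLS branch-length estimates for a fixed topology.

    Solves min ||A b - d|| over the leaf-pair path incidence matrix A.
    Returns (lengths per edge, edges, raw total, residual sum of squares).
    """
    edges = _edges(adj)
    eidx = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.empty(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in _leaf_path(adj, i, j):
            A[r, eidx[e]] = 1.0
        y[r] = d[i, j]
    lengths, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(((A @ lengths - y) ** 2).sum())
    return lengths, edges, float(lengths.sum()), resid


def _enumerate_topologies(n: int):
    """Yield all unrooted binary topologies on leaves 0..n-1 ((2n-5)!! of them)."""
    hub = n  # internal node ids start at n
    base: Adjacency = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    if n == 3:
        yield base
        return

    def insert(adj: Adjacency, leaf: int, next_internal: int):
        for u, v in _edges(adj):
            new = {k: list(vs) for k, vs in adj.items()}
            w = next_internal
            new[u] = [w if x == v else x for x in new[u]]
            new[v] = [w if x == u else x for x in new[v]]
            new[w] = [u, v, leaf]
            new[leaf] = [w]
            if leaf == n - 1:
                yield new
            else:
                yield from insert(new, leaf + 1, next_internal + 1)

    yield from insert(base, 3, n + 1)


def _nj_adjacency(dm: DistanceMatrix) -> Adjacency:
    """Neighbor-joining starting topology as an adjacency over leaf indices."""
    tree = nj(dm)
    leaf_index = {name: i for i, name in enumerate(dm.ids)}
    adj: Adjacency = {}
    next_id = [len(dm.ids)]
    node_id: dict[int, int] = {}

    def get_id(node) -> int:
        key = id(node)
        if key not in node_id:
            if node.is_tip():
                node_id[key] = leaf_index[node.name]
            else:
                node_id[key] = next_id[0]
                next_id[0] += 1
        return node_id[key]

    for node in tree.traverse(include_self=True):
        u = get_id(node)
        adj.setdefault(u, [])
        for child in node.children:
            v = get_id(child)
            adj.setdefault(v, [])
            adj[u].append(v)
            adj[v].append(u)

    # suppress degree-2 nodes (a rooted NJ representation's root)
    for u in [u for u in list(adj) if len(adj[u]) == 2]:
        a, b = adj.pop(u)
        adj[a] = [b if x == u else x for x in adj[a]]
        adj[b] = [a if x == u else x for x in adj[b]]
    return adj


def _nni_neighbors(adj: Adjacency):
    """The two nearest-neighbor-interchange rearrangements per internal edge."""
    for u, v in _edges(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        a, b = [x for x in adj[u] if x != v]
        c, dn = [x for x in adj[v] if x != u]
        for x, y in ((b, c), (b, dn)):
            new = {k: list(vs) for k, vs in adj.items()}
            new[u] = [y if t == x else t for t in new[u]]
            new[v] = [x if t == y else t for t in new[v]]
            new[x] = [v if t == u else t for t in new[x]]
            new[y] = [u if t == v else t for t in new[y]]
            yield new


@dataclass
class PhyloTree:
    """Unrooted ME tree with OLS branch lengths.

    ``total_length`` sums the displayed (zero-truncated) branch lengths;
    ``ols_total`` is the raw OLS objective used for topology search.
    ``max_pairwise_distance`` is the longest input distance, reported as the
    scale reference printed under each per-patient tree.
    """

    ids: list[str]
    tree: TreeNode
    total_length: float
    ols_total: float
    ols_residual: float
    n_negative_truncated: int
    max_pairwise_distance: float

    def newick(self) -> str:
        return str(self.tree).strip()


def _to_treenode(adj: Adjacency, lengths: dict[tuple[int, int], float], ids: list[str]) -> TreeNode:
    n = len(ids)
    root = max(adj)  # an internal node

    def build(u: int, parent: int | None) -> TreeNode:
        node = TreeNode(name=ids[u] if u < n else None)
        if parent is not None:
            e = (min(u, parent), max(u, parent))
            node.length = max(0.0, lengths[e])
        for v in adj[u]:
            if v != parent:
                node.append(build(v, u))
        return node

    return build(root, None)


def build_me_tree(dist: DistanceMatrix, exhaustive_max: int = EXHAUSTIVE_MAX_LEAVES) -> PhyloTree:
    """Infer the minimal-evolution tree for a sample distance matrix.

    Exhaustive topology search for <= ``exhaustive_max`` leaves (exact ME
    under OLS); otherwise neighbor-joining start plus NNI hill-climbing.
    """
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 leaves to build a tree")
    d = np.asarray(dist.data, float)

    if n <= exhaustive_max:
        best = None
        for adj in _enumerate_topologies(n):
            lengths, edges, total, resid = ols_branch_lengths(adj, d, n)
            if best is None or total < best[2] - 1e-12:
                best = (adj, (lengths, edges), total, resid)
        adj, (lengths, edges), total, resid = best
    else:
        adj = _nj_adjacency(dist)
        lengths, edges, total, resid = ols_branch_lengths(adj, d, n)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(adj):
                cl, ce, ct, cr = ols_branch_lengths(cand, d, n)
                if ct < total - 1e-12:
                    adj, lengths, edges, total, resid = cand, cl, ce, ct, cr
                    improved = True
                    break

    length_map = dict(zip(edges, lengths))
    n_neg = int((lengths < 0).sum())
    if n_neg:
        log.warning("%d negative OLS branch lengths truncated to 0", n_neg)
    tree = _to_treenode(adj, length_map, ids)
    return PhyloTree(
        ids=ids,
        tree=tree,
        total_length=float(np.clip(lengths, 0.0, None).sum()),
        ols_total=total,
        ols_residual=resid,
        n_negative_truncated=n_neg,
        max_pairwise_distance=float(d.max()),
    )
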