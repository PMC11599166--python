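"""Vectorized graph-metric kernels on dense boolean adjacency matrices.

Permutation inference recomputes group networks and metrics thousands of
times, so the hot path avoids per-call graph objects: adjacency matrices
are small dense arrays (N <= ~100 regions) and metrics reduce to matrix
products and BFS level sets.  Correctness of every kernel is pinned against
exhaustive brute-force oracles and networkx in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bfs_distances",
    "degrees",
    "triangles_per_node",
    "local_clustering",
    "mean_clustering",
    "transitivity",
    "global_efficiency",
    "char_path_length",
    "local_efficiency",
    "degree_assortativity",
    "largest_component_fraction",
    "adjacency_from_order",
    "rank_upper_entries",
]


def degrees(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=0).astype(np.int64)


def triangles_per_node(a: np.ndarray) -> np.ndarray:
    """Number of triangles through each node: diag(A^3)/2."""
    af = a.astype(np.float64)
    a3 = af @ af @ af
    return np.round(np.diag(a3) / 2.0).astype(np.int64)


def local_clustering(a: np.ndarray) -> np.ndarray:
    """c_i = 2 t_i / (k_i (k_i - 1)); zero where k_i < 2."""
    k = degrees(a)
    t = triangles_per_node(a)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return c


def mean_clustering(a: np.ndarray) -> float:
    return float(local_clustering(a).mean())


def transitivity(a: np.ndarray) -> float:
    """3 * triangles / connected triples = trace(A^3) / sum k(k-1)."""
    k = degrees(a)
    triples = int((k * (k - 1)).sum())
    if triples == 0:
        return 0.0
    af = a.astype(np.float64)
    closed = float(np.trace(af @ af @ af))  # = 6 * n_triangles
    return closed / triples


def bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of an unweighted graph.

    Dense BFS by boolean matrix powers — for the small dense networks here
    the diameter is tiny, so a handful of N^3 products beats per-source
    traversal.  Unreachable pairs get +inf.
    """
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = a.astype(bool)
    np.fill_diagonal(reach, True)
    frontier = a.astype(bool)
    d = 1
    while frontier.any():
        dist[frontier] = d
        nxt = (reach.astype(np.float64) @ a.astype(np.float64)) > 0
        frontier = nxt & ~reach
        reach |= nxt
        d += 1
    return dist


def global_efficiency(a: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Mean over ordered node pairs of 1/d_ij; disconnected pairs count 0."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    if dist is None:
        dist = bfs_distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def char_path_length(a: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Harmonic-mean path length: n_pairs / sum(1/d_ij).

    The exact reciprocal of global efficiency; +inf on an empty graph.
    """
    eg = global_efficiency(a, dist)
    return 1.0 / eg if eg > 0 else float("inf")


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph."""
    n = a.shape[0]
    k = degrees(a)
    total = 0.0
    ab = a.astype(bool)
    for i in range(n):
        if k[i] < 2:
            continue
        nbrs = np.flatnonzero(ab[i])
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def degree_assortativity(a: np.ndarray) -> float:
    """Pearson correlation of end-node degrees over edges; NaN if degenerate."""
    k = degrees(a).astype(np.float64)
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size == 0:
        return float("nan")
    # each undirected edge contributes both orientations
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    sx = x.std()
    if sx == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def largest_component_fraction(a: np.ndarray, n_original: int | None = None) -> float:
    """Size of the largest connected component over the original node count."""
    n = a.shape[0]
    if n_original is None:
        n_original = n
    if n == 0:
        return 0.0
    reach = a.astype(bool)
    np.fill_diagonal(reach, True)
    prev = np.zeros_like(reach)
    while (reach != prev).any():
        prev = reach
        reach = (reach.astype(np.float64) @ reach.astype(np.float64)) > 0
    best = int(reach.sum(axis=1).max())
    return best / n_original


def rank_upper_entries(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle (i, j, value) sorted by descending value then (i, j)."""
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def adjacency_from_order(
    iu: np.ndarray, ju: np.ndarray, n_edges: int, n_nodes: int
) -> np.ndarray:
    """Boolean adjacency keeping the first ``n_edges`` ranked index pairs."""
    a = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    a[iu[:n_edges], ju[:n_edges]] = 1
    a |= a.T
    return a
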