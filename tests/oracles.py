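"""Independent brute-force oracles used to pin the package's computations.

Everything here is deliberately naive — exhaustive enumeration over tiny
graphs and direct textbook formulas — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bf_neighbors(a, v):
    return [u for u in range(len(a)) if a[v][u]]


def bf_components(a) -> list[set[int]]:
    """Connected components by breadth-first search."""
    n = len(a)
    seen = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        comp = {s}
        q = deque([s])
        while q:
            v = q.popleft()
            for u in bf_neighbors(a, v):
                if u not in comp:
                    comp.add(u)
                    q.append(u)
        seen |= comp
        comps.append(comp)
    return comps


def bf_all_shortest_paths(a, s, t) -> list[tuple[int, ...]]:
    """All shortest s-t paths by enumerating simple paths (tiny graphs only)."""
    n = len(a)
    if s == t:
        return []
    best: list[tuple[int, ...]] = []
    best_len = n + 1

    def extend(path):
        nonlocal best, best_len
        v = path[-1]
        if v == t:
            L = len(path) - 1
            if L < best_len:
                best, best_len = [tuple(path)], L
            elif L == best_len:
                best.append(tuple(path))
            return
        if len(path) - 1 >= best_len:
            return
        for u in bf_neighbors(a, v):
            if u not in path:
                extend(path + [u])

    extend([s])
    return best


def bf_betweenness(a) -> np.ndarray:
    """Betweenness by explicit shortest-path enumeration, normalized by
    (N-1)(N-2)/2."""
    n = len(a)
    acc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = bf_all_shortest_paths(a, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                acc[v] += 1.0 / len(paths)
    return acc / ((n - 1) * (n - 2) / 2.0)


def bf_triangles(a) -> int:
    n = len(a)
    return sum(
        1
        for i, j, k in itertools.combinations(range(n), 3)
        if a[i][j] and a[j][k] and a[i][k]
    )


def bf_triangles_per_node(a) -> np.ndarray:
    n = len(a)
    out = np.zeros(n, dtype=int)
    for i, j, k in itertools.combinations(range(n), 3):
        if a[i][j] and a[j][k] and a[i][k]:
            out[i] += 1
            out[j] += 1
            out[k] += 1
    return out


def bf_connected_triples(a) -> int:
    """Paths of length two (ordered center, unordered ends)."""
    n = len(a)
    total = 0
    for v in range(n):
        k = len(bf_neighbors(a, v))
        total += k * (k - 1)  # ordered pairs of distinct neighbors
    return total


def bf_transitivity(a) -> float:
    triples = bf_connected_triples(a)
    if triples == 0:
        return 0.0
    return 6.0 * bf_triangles(a) / triples


def bf_clustering(a) -> np.ndarray:
    n = len(a)
    t = bf_triangles_per_node(a)
    out = np.zeros(n)
    for v in range(n):
        k = len(bf_neighbors(a, v))
        if k >= 2:
            out[v] = 2.0 * t[v] / (k * (k - 1))
    return out


def bf_shortest_path_length(a, s, t) -> float:
    """BFS distance; inf when unreachable."""
    if s == t:
        return 0.0
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for u in bf_neighbors(a, v):
            if u not in dist:
                dist[u] = dist[v] + 1
                if u == t:
                    return float(dist[u])
                q.append(u)
    return float("inf")


def bf_global_efficiency(a) -> float:
    n = len(a)
    total = 0.0
    for s, t in itertools.permutations(range(n), 2):
        d = bf_shortest_path_length(a, s, t)
        if np.isfinite(d) and d > 0:
            total += 1.0 / d
    return total / (n * (n - 1))


def bf_largest_component_curve(a, order) -> list[float]:
    """Largest-component fractions after removing nodes in the given order."""
    n = len(a)
    alive = list(range(n))
    fracs = [max(len(c) for c in bf_components(a)) / n]
    work = [row[:] for row in a]
    for v in order:
        alive.remove(v)
        for u in range(n):
            work[v][u] = work[u][v] = 0
        if not alive:
            fracs.append(0.0)
            continue
        sub = [[work[i][j] for j in alive] for i in alive]
        fracs.append(max(len(c) for c in bf_components(sub)) / n)
    return fracs


def bf_chi_square(table) -> float:
    """Pearson chi-square, no continuity correction: sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def bf_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def bf_bh_flags(p, q=0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_max = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


def bf_residuals(X, Y) -> np.ndarray:
    """OLS residuals via the normal equations."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    return Y - X @ beta


def random_adjacency(rng, n, p) -> np.ndarray:
    """Erdos-Renyi adjacency as a plain 0/1 array."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, 1).astype(np.uint8)
    return a | a.T
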