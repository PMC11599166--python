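"""Global and nodal graph metrics, degree-preserving null models, and
small-world normalization.

Conventions
-----------
* Characteristic path length L_p is the *harmonic mean* distance
  (number of ordered pairs divided by the sum of reciprocal shortest-path
  lengths).  Disconnected pairs contribute zero reciprocal distance, so
  L_p stays finite under fragmentation and E_glob * L_p == 1 identically.
* Betweenness is normalized by (N-1)(N-2)/2 (undirected convention).
* Small-world parameters compare the network to an ensemble of m
  degree-preserving rewired graphs:  gamma = C_p / C_rand,
  lambda = L_p / L_rand, sigma = gamma / lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _fast
from .construction import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "SmallWorldResult",
    "GLOBAL_METRIC_NAMES",
    "nodal_metrics",
    "global_metrics",
    "random_reference",
    "small_world",
    "modularity_best",
    "betweenness_centrality",
    "rewire_adjacency",
]

GLOBAL_METRIC_NAMES = (
    "clustering",
    "path_length",
    "global_efficiency",
    "local_efficiency",
    "transitivity",
    "modularity",
    "assortativity",
)


@dataclass(frozen=True)
class GlobalMetrics:
    clustering: float          # C_p, mean local clustering coefficient
    path_length: float         # L_p, harmonic-mean characteristic path length
    global_efficiency: float   # E_glob = 1 / L_p
    local_efficiency: float    # E_loc
    transitivity: float
    modularity: float          # best Q over seeded restarts
    assortativity: float
    density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "transitivity": self.transitivity,
            "modularity": self.modularity,
            "assortativity": self.assortativity,
            "density": self.density,
        }


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray         # integer degrees
    betweenness: np.ndarray    # normalized to [0, 1]
    clustering: np.ndarray     # local clustering coefficients
    roi_labels: tuple[str, ...]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "betweenness": self.betweenness,
            "clustering": self.clustering,
        }


@dataclass(frozen=True)
class NullEnsemble:
    members: list[np.ndarray]
    c_rand: float
    l_rand: float
    seed: int | None
    rewired: bool  # False when the graph was too rigid to swap

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SmallWorldResult:
    gamma: float   # C_p / C_rand
    lam: float     # L_p / L_rand
    sigma: float   # gamma / lambda

    def as_dict(self) -> dict[str, float]:
        return {"gamma": self.gamma, "lambda": self.lam, "sigma": self.sigma}


def betweenness_centrality(a: np.ndarray) -> np.ndarray:
    """Shortest-path betweenness, normalized by (N-1)(N-2)/2."""
    g = nx.from_numpy_array(np.asarray(a, dtype=int))
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def modularity_best(a: np.ndarray, seed: int = 0, n_restarts: int = 10) -> float:
    """Best modularity Q over seeded restarts of Louvain agglomeration."""
    g = nx.from_numpy_array(np.asarray(a, dtype=int))
    if g.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for k in range(n_restarts):
        comms = nx.community.louvain_communities(g, seed=seed + k)
        q = nx.community.modularity(g, comms)
        best = max(best, q)
    return float(best)


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """Degree, normalized betweenness and local clustering for every node."""
    a = np.asarray(net.a)
    if a.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    return NodalMetrics(
        degree=_fast.degrees(a),
        betweenness=betweenness_centrality(a),
        clustering=_fast.local_clustering(a),
        roi_labels=net.roi_labels,
    )


def global_metrics(
    net: BinaryNetwork, modularity_seed: int = 0, n_restarts: int = 10
) -> GlobalMetrics:
    """All whole-network metrics of a binary network."""
    a = np.asarray(net.a)
    if a.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    if a.sum() == 0:
        raise ValueError("empty graph: no edges")
    dist = _fast.bfs_distances(a)
    eg = _fast.global_efficiency(a, dist)
    return GlobalMetrics(
        clustering=_fast.mean_clustering(a),
        path_length=1.0 / eg if eg > 0 else float("inf"),
        global_efficiency=eg,
        local_efficiency=_fast.local_efficiency(a),
        transitivity=_fast.transitivity(a),
        modularity=modularity_best(a, seed=modularity_seed, n_restarts=n_restarts),
        assortativity=_fast.degree_assortativity(a),
        density=net.recompute_density(),
    )


def rewire_adjacency(
    a: np.ndarray, rng: np.random.Generator, swaps_per_edge: int = 10
) -> np.ndarray:
    """One degree-preserving randomization by attempted double-edge swaps.

    Attempts ``swaps_per_edge * E`` swaps; each picks two random edges
    (u, v), (x, y) and rewires to (u, x), (v, y) unless that would create a
    self-loop or duplicate edge.  The degree sequence is invariant.
    """
    a = np.array(a, dtype=np.uint8)
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = np.stack([iu, ju], axis=1)
    n_edges = len(edges)
    if n_edges < 2:
        return a
    attempts = swaps_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(attempts, 2))
    flip = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        # proposed new edges (u, x) and (v, y)
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = sorted((u, x))
        edges[e2] = sorted((v, y))
    return a


def random_reference(
    net: BinaryNetwork,
    m: int = 20,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> NullEnsemble:
    """Ensemble of m degree-preserving rewired null networks.

    C_rand and L_rand are the ensemble means of the clustering coefficient
    and the harmonic-mean path length.  A graph too rigid to rewire (e.g.
    complete) yields m identical copies and a warning.
    """
    a = np.asarray(net.a, dtype=np.uint8)
    n = a.shape[0]
    complete = net.n_edges == n * (n - 1) // 2
    rng = np.random.default_rng(seed)
    members: list[np.ndarray] = []
    any_changed = False
    for _ in range(m):
        if complete:
            member = a.copy()
        else:
            member = rewire_adjacency(a, rng, swaps_per_edge=swaps_per_edge)
        any_changed = any_changed or not np.array_equal(member, a)
        members.append(member)
    if not any_changed:
        warnings.warn(
            "graph could not be rewired (complete or rigid); null ensemble "
            "consists of identical copies",
            stacklevel=2,
        )
    c_rand = float(np.mean([_fast.mean_clustering(mb) for mb in members]))
    l_rand = float(np.mean([_fast.char_path_length(mb) for mb in members]))
    return NullEnsemble(
        members=members, c_rand=c_rand, l_rand=l_rand, seed=seed, rewired=any_changed
    )


def small_world(net: BinaryNetwork, nulls: NullEnsemble) -> SmallWorldResult:
    """gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda."""
    if nulls.c_rand <= 0 or nulls.l_rand <= 0:
        raise ValueError("null ensemble has non-positive C_rand or L_rand")
    a = np.asarray(net.a)
    cp = _fast.mean_clustering(a)
    lp = _fast.char_path_length(a)
    gamma = cp / nulls.c_rand
    lam = lp / nulls.l_rand
    return SmallWorldResult(gamma=gamma, lam=lam, sigma=gamma / lam)
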