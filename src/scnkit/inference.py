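"""Between-group inference on network metrics.

Group differences in SCN metrics cannot be tested subject-by-subject — each
group contributes a single network — so significance is assessed by
permuting group labels: subjects are reassigned to two pseudo-groups of the
original sizes, the whole construction (correlation -> density threshold ->
metric) is recomputed per labeling, and the observed difference is compared
with the permutation null.  Two-tailed p-values use the add-one rule
p = (1 + #{|null| >= |obs|}) / (1 + n_perm), and Benjamini-Hochberg FDR is
applied within families (per metric across densities, per metric across
nodes, and across metrics for the AUC summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import _fast
from .cohort import ResidualTable
from .construction import DensityGrid, edge_count_for_density
from .metrics import GLOBAL_METRIC_NAMES, betweenness_centrality, modularity_best

__all__ = [
    "MetricCurve",
    "PermutationResult",
    "metric_curves",
    "permute_groups",
    "permutation_test_global",
    "permutation_test_nodal",
    "fdr_adjust",
    "trapezoid_auc",
]

NODAL_METRIC_NAMES = ("degree", "betweenness", "clustering")


def trapezoid_auc(x: Sequence[float], y: Sequence[float]) -> float:
    """Trapezoidal area under a curve sampled at the given grid points."""
    return float(np.trapezoid(np.asarray(y, dtype=float), np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class MetricCurve:
    metric: str
    group: str
    densities: tuple[float, ...]
    values: tuple[float, ...]
    auc: float

    @classmethod
    def from_values(cls, metric, group, densities, values) -> "MetricCurve":
        densities = tuple(float(d) for d in densities)
        values = tuple(float(v) for v in values)
        if any(b <= a for a, b in zip(densities, densities[1:])):
            raise ValueError("densities must be strictly increasing")
        return cls(metric, group, densities, values, trapezoid_auc(densities, values))


@dataclass(frozen=True)
class PermutationResult:
    metric: str
    scope: str                # "global-density" | "global-auc" | "nodal-dmin" | "nodal-auc"
    location: str             # density (as string) or ROI label
    observed: float           # group1 - group2
    null: np.ndarray = field(repr=False)
    p_value: float
    fdr_significant: bool
    n_perm: int
    seed: int | None

    def to_dict(self, keep_null: bool = False) -> dict:
        d = {
            "metric": self.metric,
            "scope": self.scope,
            "location": self.location,
            "observed": self.observed,
            "p_value": self.p_value,
            "fdr_significant": bool(self.fdr_significant),
            "n_perm": self.n_perm,
        }
        if keep_null:
            d["null"] = self.null.tolist()
        return d


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q; boolean flags in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def permute_groups(
    labels: Sequence, n_perm: int, seed: int | None = None
) -> Iterator[np.ndarray]:
    """Stream of ``n_perm`` random shuffles of a group-label vector.

    Each yielded array reassigns the subjects to two pseudo-groups while
    preserving the original group sizes.  Shuffling the *labels* (rather
    than drawing index splits) makes inference exactly invariant to
    swapping the two group names: the permutation stream is identical and
    only the roles of the pseudo-groups exchange.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    for _ in range(n_perm):
        yield labels[rng.permutation(n)]


def _two_tailed_p(observed: float, null: np.ndarray) -> float:
    if not np.isfinite(observed):
        return float("nan")
    null = null[np.isfinite(null)]
    n = len(null)
    return (1.0 + int((np.abs(null) >= abs(observed)).sum())) / (1.0 + n)


# ---------------------------------------------------------------------------
# fast per-labeling metric evaluation

def _metric_value(a: np.ndarray, name: str, dist: np.ndarray | None,
                  modularity_seed: int) -> float:
    if name == "clustering":
        return _fast.mean_clustering(a)
    if name == "path_length":
        return _fast.char_path_length(a, dist)
    if name == "global_efficiency":
        return _fast.global_efficiency(a, dist)
    if name == "local_efficiency":
        return _fast.local_efficiency(a)
    if name == "transitivity":
        return _fast.transitivity(a)
    if name == "assortativity":
        return _fast.degree_assortativity(a)
    if name == "modularity":
        return modularity_best(a, seed=modularity_seed)
    raise KeyError(f"unknown global metric {name!r}")


def _needs_distances(metric_names: Sequence[str]) -> bool:
    return bool({"path_length", "global_efficiency"} & set(metric_names))


def _group_global_curves(
    X: np.ndarray,
    idx: np.ndarray,
    densities: Sequence[float],
    metric_names: Sequence[str],
    modularity_seed: int,
) -> dict[str, np.ndarray]:
    """Metric-per-density arrays for one subject subset, correlation ranked once."""
    n_nodes = X.shape[1]
    r = np.corrcoef(X[idx], rowvar=False)
    iu, ju, vals = _fast.rank_upper_entries(r)
    n_pos = int((vals > 0).sum())
    out = {m: np.empty(len(densities)) for m in metric_names}
    need_d = _needs_distances(metric_names)
    for di, d in enumerate(densities):
        e = edge_count_for_density(d, n_nodes)
        if e > n_pos:
            raise ValueError(
                f"density {d} needs {e} edges but only {n_pos} positive "
                f"correlations are available"
            )
        a = _fast.adjacency_from_order(iu, ju, e, n_nodes)
        dist = _fast.bfs_distances(a) if need_d else None
        for m in metric_names:
            out[m][di] = _metric_value(a, m, dist, modularity_seed)
    return out


def _group_nodal_values(
    X: np.ndarray,
    idx: np.ndarray,
    densities: Sequence[float],
    metric_names: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-node metric arrays, shape (n_density, n_nodes), for one subset."""
    n_nodes = X.shape[1]
    r = np.corrcoef(X[idx], rowvar=False)
    iu, ju, vals = _fast.rank_upper_entries(r)
    n_pos = int((vals > 0).sum())
    out = {m: np.empty((len(densities), n_nodes)) for m in metric_names}
    for di, d in enumerate(densities):
        e = edge_count_for_density(d, n_nodes)
        if e > n_pos:
            raise ValueError(f"density {d} unreachable with positive correlations")
        a = _fast.adjacency_from_order(iu, ju, e, n_nodes)
        for m in metric_names:
            if m == "degree":
                out[m][di] = _fast.degrees(a)
            elif m == "clustering":
                out[m][di] = _fast.local_clustering(a)
            elif m == "betweenness":
                out[m][di] = betweenness_centrality(a)
            else:
                raise KeyError(f"unknown nodal metric {m!r}")
    return out


# ---------------------------------------------------------------------------
# observed curves

def metric_curves(
    residuals: ResidualTable,
    groups: tuple[str, str] | None = None,
    grid: DensityGrid | None = None,
    metrics: Sequence[str] = GLOBAL_METRIC_NAMES,
    include_small_world: bool = True,
    m_nulls: int = 20,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    modularity_seed: int = 0,
) -> list[MetricCurve]:
    """Observed per-group metric curves over the density grid, with AUCs.

    When ``include_small_world`` is true, gamma/lambda/sigma are appended,
    each density point normalized by its own null ensemble of ``m_nulls``
    degree-preserving rewirings.
    """
    if grid is None:
        grid = DensityGrid()
    if groups is None:
        groups = residuals.group_levels
    densities = list(grid)
    X = residuals.values()
    curves: list[MetricCurve] = []
    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(len(groups))
    for gi, g in enumerate(groups):
        idx = residuals.group_indices(g)
        vals = _group_global_curves(X, idx, densities, metrics, modularity_seed)
        for m in metrics:
            curves.append(MetricCurve.from_values(m, g, densities, vals[m]))
        if include_small_world:
            sw = _small_world_curves(
                X, idx, densities, m_nulls, swaps_per_edge, group_seeds[gi]
            )
            for m in ("gamma", "lambda", "sigma"):
                curves.append(MetricCurve.from_values(m, g, densities, sw[m]))
    return curves


def _small_world_curves(X, idx, densities, m_nulls, swaps_per_edge, seedseq):
    from .metrics import rewire_adjacency

    n_nodes = X.shape[1]
    r = np.corrcoef(X[idx], rowvar=False)
    iu, ju, _ = _fast.rank_upper_entries(r)
    rng = np.random.default_rng(seedseq)
    out = {"gamma": [], "lambda": [], "sigma": []}
    for d in densities:
        e = edge_count_for_density(d, n_nodes)
        a = _fast.adjacency_from_order(iu, ju, e, n_nodes)
        cp = _fast.mean_clustering(a)
        lp = _fast.char_path_length(a)
        cs, ls = [], []
        for _ in range(m_nulls):
            member = rewire_adjacency(a, rng, swaps_per_edge=swaps_per_edge)
            cs.append(_fast.mean_clustering(member))
            ls.append(_fast.char_path_length(member))
        gamma = cp / np.mean(cs)
        lam = lp / np.mean(ls)
        out["gamma"].append(gamma)
        out["lambda"].append(lam)
        out["sigma"].append(gamma / lam)
    return out


# ---------------------------------------------------------------------------
# permutation tests

def permutation_test_global(
    residuals: ResidualTable,
    groups: tuple[str, str] | None = None,
    grid: DensityGrid | None = None,
    metrics: Sequence[str] = GLOBAL_METRIC_NAMES,
    n_perm: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
    modularity_seed: int = 0,
) -> list[PermutationResult]:
    """Permutation tests on global metrics, per density and on AUCs.

    Returns one result per (metric, density) in scope ``global-density``
    plus one per metric in scope ``global-auc``.  FDR families: each metric
    across the grid densities, and the AUC tests across metrics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = DensityGrid()
    if groups is None:
        groups = residuals.group_levels
    densities = list(grid)
    X = residuals.values()
    idx1 = residuals.group_indices(groups[0])
    idx2 = residuals.group_indices(groups[1])

    def diff_curves(i1, i2):
        v1 = _group_global_curves(X, i1, densities, metrics, modularity_seed)
        v2 = _group_global_curves(X, i2, densities, metrics, modularity_seed)
        return {m: v1[m] - v2[m] for m in metrics}

    obs = diff_curves(idx1, idx2)
    null_density = {m: np.empty((n_perm, len(densities))) for m in metrics}
    pooled = np.sort(np.concatenate([idx1, idx2]))
    in_g1 = np.isin(pooled, idx1)
    for pi, lab in enumerate(permute_groups(in_g1, n_perm, seed)):
        d = diff_curves(pooled[lab], pooled[~lab])
        for m in metrics:
            null_density[m][pi] = d[m]

    results: list[PermutationResult] = []
    for m in metrics:
        ps = []
        for di, dens in enumerate(densities):
            null = null_density[m][:, di]
            p = _two_tailed_p(obs[m][di], null)
            ps.append(p)
            results.append(
                PermutationResult(
                    metric=m, scope="global-density", location=f"{dens:g}",
                    observed=float(obs[m][di]), null=null, p_value=p,
                    fdr_significant=False, n_perm=n_perm, seed=seed,
                )
            )
        flags = fdr_adjust(np.nan_to_num(np.asarray(ps), nan=1.0), q)
        for flag, res in zip(flags, results[-len(densities):]):
            object.__setattr__(res, "fdr_significant", bool(flag))

    # AUC family: one test per metric across the whole grid
    auc_results: list[PermutationResult] = []
    dens_arr = np.asarray(densities)
    for m in metrics:
        obs_auc = trapezoid_auc(dens_arr, obs[m])
        null_auc = np.trapezoid(null_density[m], dens_arr, axis=1)
        p = _two_tailed_p(obs_auc, null_auc)
        auc_results.append(
            PermutationResult(
                metric=m, scope="global-auc", location="auc",
                observed=obs_auc, null=null_auc, p_value=p,
                fdr_significant=False, n_perm=n_perm, seed=seed,
            )
        )
    flags = fdr_adjust(
        np.nan_to_num(np.asarray([r.p_value for r in auc_results]), nan=1.0), q
    )
    for flag, res in zip(flags, auc_results):
        object.__setattr__(res, "fdr_significant", bool(flag))
    return results + auc_results


def permutation_test_nodal(
    residuals: ResidualTable,
    groups: tuple[str, str] | None = None,
    grid: DensityGrid | None = None,
    scope: str = "nodal-dmin",
    metrics: Sequence[str] = NODAL_METRIC_NAMES,
    n_perm: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
) -> list[PermutationResult]:
    """Permutation tests on per-node metrics.

    ``scope='nodal-dmin'`` tests node values at the grid's minimum density;
    ``scope='nodal-auc'`` tests per-node AUCs over the full grid.  FDR is
    applied per metric across the N nodes.
    """
    if scope not in {"nodal-dmin", "nodal-auc"}:
        raise ValueError(f"unknown nodal scope {scope!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if grid is None:
        grid = DensityGrid()
    if groups is None:
        groups = residuals.group_levels
    densities = [grid.d_min] if scope == "nodal-dmin" else list(grid)
    dens_arr = np.asarray(densities)
    X = residuals.values()
    labels = residuals.roi_labels
    idx1 = residuals.group_indices(groups[0])
    idx2 = residuals.group_indices(groups[1])

    def node_stats(i1, i2):
        v1 = _group_nodal_values(X, i1, densities, metrics)
        v2 = _group_nodal_values(X, i2, densities, metrics)
        out = {}
        for m in metrics:
            diff = v1[m] - v2[m]  # (n_density, n_nodes)
            if scope == "nodal-dmin":
                out[m] = diff[0]
            else:
                out[m] = np.trapezoid(diff, dens_arr, axis=0)
        return out

    obs = node_stats(idx1, idx2)
    n_nodes = X.shape[1]
    null = {m: np.empty((n_perm, n_nodes)) for m in metrics}
    pooled = np.sort(np.concatenate([idx1, idx2]))
    in_g1 = np.isin(pooled, idx1)
    for pi, lab in enumerate(permute_groups(in_g1, n_perm, seed)):
        d = node_stats(pooled[lab], pooled[~lab])
        for m in metrics:
            null[m][pi] = d[m]

    results: list[PermutationResult] = []
    for m in metrics:
        ps = [
            _two_tailed_p(obs[m][ni], null[m][:, ni]) for ni in range(n_nodes)
        ]
        flags = fdr_adjust(np.nan_to_num(np.asarray(ps), nan=1.0), q)
        for ni in range(n_nodes):
            results.append(
                PermutationResult(
                    metric=m, scope=scope, location=labels[ni],
                    observed=float(obs[m][ni]), null=null[m][:, ni],
                    p_value=ps[ni], fdr_significant=bool(flags[ni]),
                    n_perm=n_perm, seed=seed,
                )
            )
    return results
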