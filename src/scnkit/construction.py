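"""Construction of structural covariance networks.

A structural covariance network (SCN) is a group-level graph: each node is a
brain region and each edge weight r_ij is the Pearson correlation, across
the subjects of one group, between the covariate-adjusted gray-matter
volumes of regions i and j.  The weighted matrix is binarized either by a
fixed absolute cutoff or — for between-group comparability — by choosing
the per-group cutoff that achieves a target network density
D = E / [N(N-1)/2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .cohort import ResidualTable

__all__ = [
    "CovarianceNetwork",
    "BinaryNetwork",
    "DensityGrid",
    "correlation_network",
    "threshold_absolute",
    "threshold_density",
    "min_connected_density",
    "edge_count_for_density",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 1321.65 * edges arithmetic is stable)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def edge_count_for_density(density: float, n_nodes: int) -> int:
    """Number of edges E = round(D * N(N-1)/2), half away from zero."""
    return _round_half_away(density * n_nodes * (n_nodes - 1) / 2.0)


@dataclass(frozen=True)
class DensityGrid:
    """Ordered grid of network densities, generated by integer stepping.

    Defaults follow the common choice for gray-matter SCNs: from the
    minimum density that keeps both group networks connected (0.33) up to
    0.50, beyond which edges lose biological plausibility, in steps of 0.01.
    """

    d_min: float = 0.33
    d_max: float = 0.50
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max <= 1):
            raise ValueError(f"invalid density bounds: {self.d_min}..{self.d_max}")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def decimals(self) -> int:
        def places(x: float) -> int:
            s = f"{x:.10f}".rstrip("0")
            return len(s.split(".")[1]) if "." in s else 0

        return max(places(self.step), places(self.d_min))

    @property
    def densities(self) -> tuple[float, ...]:
        # integer stepping anchored at d_min, to avoid float drift
        nd = self.decimals
        scale = 10 ** nd
        lo = round(self.d_min * scale)
        hi = round(self.d_max * scale)
        step = round(self.step * scale)
        return tuple((lo + k * step) / scale for k in range((hi - lo) // step + 1))

    def __len__(self) -> int:
        return len(self.densities)

    def __iter__(self):
        return iter(self.densities)


@dataclass(frozen=True)
class CovarianceNetwork:
    """Per-group N x N Pearson correlation matrix over ROI residuals."""

    r: np.ndarray
    roi_labels: tuple[str, ...]
    group: str
    n_subjects: int

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.roi_labels, columns=self.roi_labels)


@dataclass(frozen=True)
class BinaryNetwork:
    """Symmetric 0/1 adjacency with zero diagonal at a given density."""

    a: np.ndarray
    density: float
    provenance: str = "unspecified"
    roi_labels: tuple[str, ...] = field(default_factory=tuple)
    group: str = ""

    def __post_init__(self):
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def recompute_density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2.0)

    def to_frame(self) -> pd.DataFrame:
        labels = self.roi_labels or tuple(map(str, range(self.n_nodes)))
        return pd.DataFrame(self.a.astype(int), index=labels, columns=labels)

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.a, 1))
        return list(zip(iu.tolist(), ju.tolist()))

    def to_graph(self):
        import networkx as nx

        g = nx.from_numpy_array(np.asarray(self.a, dtype=int))
        if self.roi_labels:
            nx.set_node_attributes(g, dict(enumerate(self.roi_labels)), "roi")
        return g

    def is_connected(self) -> bool:
        n_comp, _ = csgraph.connected_components(
            csr_matrix(self.a), directed=False
        )
        return n_comp == 1


def correlation_network(residuals: ResidualTable, group: str) -> CovarianceNetwork:
    """Pearson correlation matrix over one group's subjects only."""
    idx = residuals.group_indices(group)
    if len(idx) < 3:
        raise ValueError(f"group {group!r} has {len(idx)} subjects; need >= 3")
    X = residuals.values()[idx]
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance residuals for ROI {residuals.roi_labels[flat[0]]!r}"
        )
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CovarianceNetwork(
        r=r, roi_labels=tuple(residuals.roi_labels), group=group, n_subjects=len(idx)
    )


def threshold_absolute(net: CovarianceNetwork, t: float = 0.1) -> BinaryNetwork:
    """Binarize: a_ij = 1 iff r_ij > t (off-diagonal), else 0."""
    if not (-1.0 < t < 1.0):
        raise ValueError(f"threshold must be in (-1, 1), got {t}")
    a = (net.r > t).astype(np.uint8)
    np.fill_diagonal(a, 0)
    bn = BinaryNetwork(
        a=a,
        density=0.0,
        provenance=f"absolute r > {t}",
        roi_labels=net.roi_labels,
        group=net.group,
    )
    object.__setattr__(bn, "density", bn.recompute_density())
    return bn


def ranked_edges(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle entries sorted by descending r, ties by (i, j).

    Returns (i, j, r_ij) arrays in retention order; the deterministic
    tie-break makes density thresholding monotone and platform-stable.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def threshold_density(net: CovarianceNetwork, density: float) -> BinaryNetwork:
    """Keep the E = round(D * N(N-1)/2) largest correlations as edges.

    Only strictly positive correlations may become edges; requesting a
    density that cannot be reached with positive entries is an error.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = net.n_nodes
    e = edge_count_for_density(density, n)
    iu, ju, vals = ranked_edges(net.r)
    n_pos = int((vals > 0).sum())
    if e > n_pos:
        raise ValueError(
            f"density {density} needs {e} edges but only {n_pos} positive "
            f"correlations are available"
        )
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[:e], ju[:e]] = 1
    a |= a.T
    bn = BinaryNetwork(
        a=a,
        density=0.0,
        provenance=f"density {density}",
        roi_labels=net.roi_labels,
        group=net.group,
    )
    object.__setattr__(bn, "density", bn.recompute_density())
    return bn


def min_connected_density(net: CovarianceNetwork, grid: DensityGrid) -> float | None:
    """Smallest grid density whose thresholded network is fully connected.

    Returns ``None`` when no grid density yields a single component
    spanning all nodes (including when a density is unreachable with
    positive correlations).
    """
    for d in grid:
        try:
            bn = threshold_density(net, d)
        except ValueError:
            continue
        if bn.is_connected():
            return d
    return None
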