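"""Hub identification and attack-robustness analysis.

Hubs are nodes whose betweenness centrality (summarized as its AUC across
the density grid) exceeds the network mean by more than two sample standard
deviations.  Robustness is probed by sequential node removal — targeted
(always the currently highest-degree node) or random — tracking the
relative size of the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _fast
from .construction import BinaryNetwork

__all__ = [
    "HubSet",
    "RobustnessCurve",
    "identify_hubs",
    "targeted_attack",
    "random_attack",
]


@dataclass(frozen=True)
class HubSet:
    hubs: tuple[str, ...]
    values: np.ndarray
    roi_labels: tuple[str, ...]
    mean: float
    sd: float
    threshold: float         # mean + 2 * sd
    basis: str

    def to_dict(self) -> dict:
        return {
            "hubs": list(self.hubs),
            "mean": self.mean,
            "sd": self.sd,
            "threshold": self.threshold,
            "basis": self.basis,
            "values": {l: float(v) for l, v in zip(self.roi_labels, self.values)},
        }


@dataclass(frozen=True)
class RobustnessCurve:
    kind: str                          # "targeted" | "random"
    fraction_removed: np.ndarray       # starts at 0
    largest_component: np.ndarray      # relative size, starts at 1
    auc: float
    reps: int = 1
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "fraction_removed": self.fraction_removed.tolist(),
            "largest_component": self.largest_component.tolist(),
            "auc": self.auc,
            "reps": self.reps,
        }


def identify_hubs(
    values: np.ndarray,
    roi_labels: tuple[str, ...] | list[str],
    basis: str = "auc-betweenness",
) -> HubSet:
    """Flag nodes strictly above mean + 2 sample SDs of ``values``.

    ``values`` is normally the per-node AUC of betweenness centrality over
    the density grid.  With zero variance across nodes no node can stand
    out and the hub set is empty (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 nodes")
    if values.size != len(roi_labels):
        raise ValueError("values and roi_labels length mismatch")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        warnings.warn("zero variance across nodes; hub set is empty", stacklevel=2)
        hubs: tuple[str, ...] = ()
        threshold = mean
    else:
        threshold = mean + 2.0 * sd
        hubs = tuple(
            l for l, v in zip(roi_labels, values) if v > threshold
        )
    return HubSet(
        hubs=hubs, values=values, roi_labels=tuple(roi_labels),
        mean=mean, sd=sd, threshold=threshold, basis=basis,
    )


def _attack_curve(a: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Largest-component fractions after removing nodes in the given order."""
    n = a.shape[0]
    alive = np.ones(n, dtype=bool)
    fracs = np.empty(n + 1)
    fracs[0] = _fast.largest_component_fraction(a, n)
    for step, node in enumerate(order, start=1):
        alive[node] = False
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            fracs[step] = 0.0
        else:
            sub = a[np.ix_(idx, idx)]
            fracs[step] = _fast.largest_component_fraction(sub, n)
    return fracs


def targeted_attack(net: BinaryNetwork) -> RobustnessCurve:
    """Adaptive degree-targeted attack.

    Repeatedly removes the currently highest-degree node (degrees
    recomputed after every removal; ties broken by lowest node index) and
    records the largest-component fraction after each step.
    """
    a = np.asarray(net.a, dtype=np.uint8)
    n = a.shape[0]
    if not net.is_connected():
        warnings.warn("targeted attack on a fragmented network", stacklevel=2)
    work = a.copy()
    alive = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=int)
    fracs = np.empty(n + 1)
    fracs[0] = _fast.largest_component_fraction(a, n)
    for step in range(n):
        deg = work.sum(axis=0).astype(np.int64)
        deg[~alive] = -1
        node = int(np.argmax(deg))  # argmax takes the lowest index on ties
        order[step] = node
        alive[node] = False
        work[node, :] = 0
        work[:, node] = 0
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            fracs[step + 1] = 0.0
        else:
            fracs[step + 1] = _fast.largest_component_fraction(
                work[np.ix_(idx, idx)], n
            )
    frac_removed = np.arange(n + 1) / n
    return RobustnessCurve(
        kind="targeted",
        fraction_removed=frac_removed,
        largest_component=fracs,
        auc=float(np.trapezoid(fracs, frac_removed)),
    )


def random_attack(
    net: BinaryNetwork, reps: int = 100, seed: int | None = None
) -> RobustnessCurve:
    """Mean robustness curve over seeded uniformly random removal orders."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    a = np.asarray(net.a, dtype=np.uint8)
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n + 1)
    for _ in range(reps):
        order = rng.permutation(n)
        acc += _attack_curve(a, order)
    fracs = acc / reps
    frac_removed = np.arange(n + 1) / n
    return RobustnessCurve(
        kind="random",
        fraction_removed=frac_removed,
        largest_component=fracs,
        auc=float(np.trapezoid(fracs, frac_removed)),
        reps=reps,
        seed=seed,
    )
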