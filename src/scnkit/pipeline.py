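"""End-to-end orchestration: cohort -> networks -> metrics -> inference ->
hubs -> robustness, behind a single serializable configuration.

Every stochastic stage receives a seed derived deterministically from one
master seed, so a saved config re-runs to an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import demographics as run_demographics
from .cohort import load_cohort, residualize
from .construction import (
    DensityGrid,
    correlation_network,
    min_connected_density,
    threshold_density,
)
from .hubs import identify_hubs, random_attack, targeted_attack
from .inference import (
    MetricCurve,
    metric_curves,
    permutation_test_global,
    permutation_test_nodal,
)
from .metrics import GLOBAL_METRIC_NAMES
from .inference import _group_nodal_values  # shared fast kernel
from .synthetic import generate, scenario

logger = logging.getLogger("scnkit")

__all__ = ["RunConfig", "AnalysisReport", "run"]

_STAGES = (
    "synthetic",
    "small_world",
    "perm_global",
    "perm_nodal_dmin",
    "perm_nodal_auc",
    "random_attack",
)


def _stage_seeds(master: int | None) -> dict[str, int | None]:
    if master is None:
        return {s: None for s in _STAGES}
    state = np.random.SeedSequence(master).generate_state(len(_STAGES))
    return {s: int(v) & 0x7FFFFFFF for s, v in zip(_STAGES, state)}


@dataclass(frozen=True)
class RunConfig:
    """Full specification of one analysis run."""

    input: str | None = None             # cohort CSV/TSV path ...
    scenario: str | None = None          # ... or synthetic scenario name
    roi_prefix: str | None = "vol_"
    roi_columns: tuple[str, ...] | None = None
    covariates: tuple[str, ...] = ("age", "sex", "tiv")
    d_min: float = 0.33
    d_max: float = 0.50
    step: float = 0.01
    n_perm: int = 1000
    m_nulls: int = 20
    swaps_per_edge: int = 10
    seed: int | None = None
    out_dir: str | None = None
    permutation_metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
    run_demographics: bool = True
    run_small_world: bool = True
    run_global_inference: bool = True
    nodal_scopes: tuple[str, ...] = ("nodal-dmin", "nodal-auc")
    run_hubs: bool = True
    run_robustness: bool = True
    robustness_reps: int = 100
    export_adjacency: bool = False

    def grid(self) -> DensityGrid:
        return DensityGrid(self.d_min, self.d_max, self.step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        clean = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            clean[k] = v
        return cls(**clean)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisReport:
    config: dict
    seeds: dict
    version: str
    group_sizes: dict[str, int]
    demographics: list[dict] | None = None
    min_connected_density: dict[str, float | None] = field(default_factory=dict)
    curves: list[dict] = field(default_factory=list)
    permutations: list[dict] = field(default_factory=list)
    hubs: dict[str, dict] = field(default_factory=dict)
    robustness: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    def significant(self, scope: str | None = None) -> list[dict]:
        out = [p for p in self.permutations if p["fdr_significant"]]
        if scope is not None:
            out = [p for p in out if p["scope"] == scope]
        return out


def _curve_dict(c: MetricCurve) -> dict:
    return {
        "metric": c.metric,
        "group": c.group,
        "densities": list(c.densities),
        "values": list(c.values),
        "auc": c.auc,
    }


def _nodal_auc_betweenness(residuals, group: str, grid: DensityGrid) -> np.ndarray:
    """Per-node AUC of betweenness centrality across the grid for one group."""
    densities = list(grid)
    vals = _group_nodal_values(
        residuals.values(), residuals.group_indices(group), densities, ("betweenness",)
    )["betweenness"]
    return np.trapezoid(vals, np.asarray(densities), axis=0)


def run(config: RunConfig) -> AnalysisReport:
    """Execute every enabled stage and return the structured report.

    When ``config.out_dir`` is set, the report JSON plus tidy delimited
    tables (curves, permutation results, robustness steps) are written
    there as well.
    """
    if (config.input is None) == (config.scenario is None):
        raise ValueError("provide exactly one of input path or scenario name")
    grid = config.grid()
    seeds = _stage_seeds(config.seed)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        if config.scenario is not None:
            spec = scenario(config.scenario, seed=seeds["synthetic"])
            logger.info("generating scenario %r", config.scenario)
            cohort = generate(spec)
        else:
            logger.info("loading cohort from %s", config.input)
            cohort = load_cohort(
                config.input,
                roi_columns=config.roi_columns,
                roi_prefix=config.roi_prefix,
            )

        report = AnalysisReport(
            config=config.to_dict(),
            seeds=dict(seeds),
            version=__version__,
            group_sizes=cohort.group_sizes(),
        )

        if config.run_demographics:
            present = set(cohort.subjects.columns)
            cont = [v for v in ("age",) if v in present]
            cat = [v for v in ("sex",) if v in present]
            if cont or cat:
                rep = run_demographics(cohort, cont, cat)
                report.demographics = rep.to_dict()

        covs = tuple(c for c in config.covariates if c in cohort.subjects.columns)
        residuals = residualize(cohort, covs)
        groups = residuals.group_levels

        for g in groups:
            net = correlation_network(residuals, g)
            report.min_connected_density[g] = min_connected_density(net, grid)

        logger.info("computing metric curves over %d densities", len(grid))
        curves = metric_curves(
            residuals,
            groups,
            grid,
            metrics=config.permutation_metrics,
            include_small_world=config.run_small_world,
            m_nulls=config.m_nulls,
            swaps_per_edge=config.swaps_per_edge,
            seed=seeds["small_world"],
        )
        report.curves = [_curve_dict(c) for c in curves]

        if config.run_global_inference:
            logger.info("global permutation tests (n_perm=%d)", config.n_perm)
            res = permutation_test_global(
                residuals, groups, grid,
                metrics=config.permutation_metrics,
                n_perm=config.n_perm, seed=seeds["perm_global"],
            )
            report.permutations += [r.to_dict() for r in res]

        for scope in config.nodal_scopes:
            logger.info("nodal permutation tests (%s)", scope)
            res = permutation_test_nodal(
                residuals, groups, grid, scope=scope,
                n_perm=config.n_perm,
                seed=seeds["perm_nodal_dmin" if scope == "nodal-dmin" else "perm_nodal_auc"],
            )
            report.permutations += [r.to_dict() for r in res]

        if config.run_hubs:
            for g in groups:
                auc_b = _nodal_auc_betweenness(residuals, g, grid)
                report.hubs[g] = identify_hubs(auc_b, residuals.roi_labels).to_dict()

        if config.run_robustness:
            for g in groups:
                net = correlation_network(residuals, g)
                bn = threshold_density(net, grid.d_min)
                report.robustness[g] = {
                    "targeted": targeted_attack(bn).to_dict(),
                    "random": random_attack(
                        bn, reps=config.robustness_reps, seed=seeds["random_attack"]
                    ).to_dict(),
                }

        captured = [str(w.message) for w in wrec]

    report.warnings = captured

    if config.out_dir is not None:
        _write_outputs(report, residuals, grid, config)
    return report


def _write_outputs(report: AnalysisReport, residuals, grid, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())

    rows = []
    for c in report.curves:
        for d, v in zip(c["densities"], c["values"]):
            rows.append({"metric": c["metric"], "group": c["group"],
                         "density": d, "value": v, "auc": c["auc"]})
    pd.DataFrame(rows).to_csv(out / "curves.tsv", sep="\t", index=False)

    if report.permutations:
        pd.DataFrame(report.permutations).to_csv(
            out / "permutations.tsv", sep="\t", index=False
        )
    if report.hubs:
        (out / "hubs.json").write_text(json.dumps(report.hubs, sort_keys=True, indent=2))
    if report.robustness:
        rows = []
        for g, kinds in report.robustness.items():
            for kind, curve in kinds.items():
                for f, s in zip(curve["fraction_removed"], curve["largest_component"]):
                    rows.append({"group": g, "kind": kind,
                                 "fraction_removed": f, "largest_component": s})
        pd.DataFrame(rows).to_csv(out / "robustness.tsv", sep="\t", index=False)

    if config.export_adjacency:
        for g in residuals.group_levels:
            net = correlation_network(residuals, g)
            bn = threshold_density(net, grid.d_min)
            bn.to_frame().to_csv(out / f"adjacency_{g}_dmin.csv")

    config.to_yaml(out / "config.yaml")
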