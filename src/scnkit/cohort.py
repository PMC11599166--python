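"""Cohort table handling: loading, validation, covariate residualization and
group demographics.

The single external input of the pipeline is a delimited table with one row
per subject carrying a subject identifier, a two-level group label,
covariates (age, sex, total intracranial volume) and one column per region
of interest (ROI) with its gray-matter volume in mm^3.  Everything
downstream consumes covariate-adjusted residuals of those regional volumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MorphometryCohort",
    "ResidualTable",
    "DemographicsEntry",
    "DemographicsReport",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "residualize",
    "demographics",
    "aal90_regions",
]

DEFAULT_COVARIATES = ("age", "sex", "tiv")


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort schema."""


@dataclass(frozen=True)
class MorphometryCohort:
    """A validated subjects x ROI morphometry table.

    Attributes
    ----------
    subjects
        Per-subject metadata with columns ``subject_id``, ``group`` and any
        covariates (``age``, ``sex``, ``tiv``).
    volumes
        Subjects x N table of strictly positive regional volumes (mm^3),
        row-aligned with ``subjects``; column order defines the ROI order.
    group_levels
        The two group labels in order of first appearance.
    """

    subjects: pd.DataFrame
    volumes: pd.DataFrame
    group_levels: tuple[str, str]

    @property
    def roi_labels(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def n_rois(self) -> int:
        return self.volumes.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_indices(self, group: str) -> np.ndarray:
        """Positional indices of the subjects belonging to ``group``."""
        if group not in self.group_levels:
            raise KeyError(f"unknown group {group!r}; levels are {self.group_levels}")
        return np.flatnonzero((self.subjects["group"] == group).to_numpy())

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.subjects["group"] == g).sum()) for g in self.group_levels}

    def validate(self) -> "MorphometryCohort":
        if len(self.subjects) != len(self.volumes):
            raise CohortValidationError("subjects and volumes are not row-aligned")
        if self.volumes.shape[1] < 3:
            raise CohortValidationError("need at least 3 ROI columns")
        if self.subjects["subject_id"].duplicated().any():
            dupes = self.subjects.loc[self.subjects["subject_id"].duplicated(), "subject_id"]
            raise CohortValidationError(f"duplicate subject ids: {sorted(set(dupes))}")
        levels = list(pd.unique(self.subjects["group"]))
        if len(levels) != 2:
            raise CohortValidationError(
                f"expected exactly two group levels, found {len(levels)}: {levels}"
            )
        for g in levels:
            n = int((self.subjects["group"] == g).sum())
            if n < 3:
                raise CohortValidationError(f"group {g!r} has {n} subjects; need >= 3")
        if self.volumes.isna().any().any() or self.subjects.isna().any().any():
            raise CohortValidationError("missing values are not allowed")
        bad = ~(self.volumes.to_numpy(dtype=float) > 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            sid = self.subjects["subject_id"].iloc[i]
            raise CohortValidationError(
                f"non-positive volume for subject {sid!r}, ROI {self.volumes.columns[j]!r}"
            )
        if "tiv" in self.subjects.columns and not (self.subjects["tiv"] > 0).all():
            raise CohortValidationError("total intracranial volume must be positive")
        if "age" in self.subjects.columns and not (self.subjects["age"] > 0).all():
            raise CohortValidationError("age must be positive")
        return self


@dataclass(frozen=True)
class ResidualTable:
    """Covariate-adjusted regional volumes.

    ``residuals`` is a subjects x N matrix of OLS residuals of each ROI's
    volume on an intercept plus the covariates, fit on the pooled cohort.
    Group labels travel along so downstream code can split by group.
    """

    residuals: pd.DataFrame
    model_terms: tuple[str, ...]
    roi_labels: tuple[str, ...]
    groups: pd.Series
    group_levels: tuple[str, str]

    def values(self) -> np.ndarray:
        return self.residuals.to_numpy(dtype=float)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in self.group_levels:
            raise KeyError(f"unknown group {group!r}; levels are {self.group_levels}")
        return np.flatnonzero((self.groups == group).to_numpy())


@dataclass(frozen=True)
class DemographicsEntry:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_summaries: dict[str, str]


@dataclass(frozen=True)
class DemographicsReport:
    entries: list[DemographicsEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"variable": e.variable, "test": e.test,
                   "statistic": e.statistic, "p_value": e.p_value}
            row.update(e.group_summaries)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> list[dict]:
        return [
            {
                "variable": e.variable,
                "test": e.test,
                "statistic": e.statistic,
                "p_value": e.p_value,
                "group_summaries": e.group_summaries,
            }
            for e in self.entries
        ]


def _resolve_roi_columns(
    columns: Sequence[str],
    roi_columns: Sequence[str] | None,
    roi_prefix: str | None,
) -> list[str]:
    if roi_columns is not None:
        missing = [c for c in roi_columns if c not in columns]
        if missing:
            raise CohortValidationError(f"ROI columns not in table: {missing}")
        return list(roi_columns)
    if roi_prefix is not None:
        found = [c for c in columns if c.startswith(roi_prefix)]
        if not found:
            raise CohortValidationError(f"no columns with ROI prefix {roi_prefix!r}")
        return found
    raise ValueError("provide either roi_columns or roi_prefix")


def load_cohort(
    path: str | Path,
    roi_columns: Sequence[str] | None = None,
    roi_prefix: str | None = "vol_",
    group_col: str = "group",
    subject_col: str = "subject_id",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> MorphometryCohort:
    """Read and validate a cohort table from a CSV/TSV file.

    ROI columns are identified either by an explicit ``roi_columns`` list or
    by a shared ``roi_prefix``.  The column order of the file defines the ROI
    order used everywhere downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)
    return cohort_from_frame(
        table,
        roi_columns=roi_columns,
        roi_prefix=roi_prefix,
        group_col=group_col,
        subject_col=subject_col,
        covariates=covariates,
    )


def cohort_from_frame(
    table: pd.DataFrame,
    roi_columns: Sequence[str] | None = None,
    roi_prefix: str | None = "vol_",
    group_col: str = "group",
    subject_col: str = "subject_id",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> MorphometryCohort:
    """Build a validated :class:`MorphometryCohort` from an in-memory frame."""
    for col in (subject_col, group_col):
        if col not in table.columns:
            raise CohortValidationError(f"required column {col!r} missing from table")
    rois = _resolve_roi_columns(table.columns, roi_columns, roi_prefix)
    meta_cols = [subject_col, group_col] + [c for c in covariates if c in table.columns]
    subjects = table[meta_cols].rename(
        columns={subject_col: "subject_id", group_col: "group"}
    )
    subjects = subjects.reset_index(drop=True)
    subjects["subject_id"] = subjects["subject_id"].astype(str)
    subjects["group"] = subjects["group"].astype(str)
    volumes = table[rois].reset_index(drop=True).astype(float)
    levels = tuple(pd.unique(subjects["group"]))
    if len(levels) != 2:
        raise CohortValidationError(
            f"expected exactly two group levels, found {len(levels)}: {list(levels)}"
        )
    cohort = MorphometryCohort(subjects=subjects, volumes=volumes, group_levels=levels)
    return cohort.validate()


def write_cohort(cohort: MorphometryCohort, path: str | Path) -> Path:
    """Write a cohort back to CSV/TSV in the schema :func:`load_cohort` reads."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.concat([cohort.subjects, cohort.volumes], axis=1)
    table.to_csv(path, sep=sep, index=False)
    return path


def _design_matrix(cohort: MorphometryCohort, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(cohort.n_subjects)]
    for name in covariates:
        if name not in cohort.subjects.columns:
            raise CohortValidationError(f"covariate {name!r} missing from cohort")
        col = cohort.subjects[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise CohortValidationError(
                    f"categorical covariate {name!r} has >2 levels: {levels}"
                )
            col = col.astype(str).map({lv: i for i, lv in enumerate(levels)})
        arr = col.to_numpy(dtype=float)
        if np.ptp(arr) == 0:
            # constant column: absorbed by the intercept, not a singularity
            continue
        cols.append(arr)
    return np.column_stack(cols)


def residualize(
    cohort: MorphometryCohort,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> ResidualTable:
    """Regress each ROI's volume on intercept + covariates; return residuals.

    The fit is ordinary least squares on the pooled cohort (both groups
    together), once, so that permutation of group labels downstream leaves
    the residuals fixed and the null exchangeable.  Sex (or any two-level
    categorical covariate) is coded 0/1 by sorted level name.
    """
    X = _design_matrix(cohort, covariates)
    n, p = X.shape
    if n < p + 2:
        raise CohortValidationError(
            f"{n} subjects cannot support {p - 1} covariates plus intercept"
        )
    if np.linalg.matrix_rank(X) < p:
        raise CohortValidationError("covariate design matrix is singular (collinear)")
    Y = cohort.volumes.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    residuals = pd.DataFrame(resid, columns=cohort.volumes.columns)
    return ResidualTable(
        residuals=residuals,
        model_terms=tuple(covariates),
        roi_labels=tuple(cohort.volumes.columns),
        groups=cohort.subjects["group"].reset_index(drop=True),
        group_levels=cohort.group_levels,
    )


def _chi_square_entry(cohort: MorphometryCohort, var: str) -> DemographicsEntry:
    table = pd.crosstab(cohort.subjects["group"], cohort.subjects[var])
    counts = table.to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise CohortValidationError(f"contingency table for {var!r} has an empty margin")
    # No Yates continuity correction: plain Pearson chi-square.
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    summaries = {}
    for g in cohort.group_levels:
        parts = [f"{int(table.loc[g, lv])}{lv}" for lv in table.columns]
        summaries[g] = "/".join(parts)
    return DemographicsEntry(var, "chi-square", float(stat), float(p), summaries)


def _continuous_entry(cohort: MorphometryCohort, var: str) -> DemographicsEntry:
    g1, g2 = cohort.group_levels
    x = cohort.subjects.loc[cohort.subjects["group"] == g1, var].to_numpy(dtype=float)
    y = cohort.subjects.loc[cohort.subjects["group"] == g2, var].to_numpy(dtype=float)
    normal = (
        stats.shapiro(x).pvalue > 0.05
        and stats.shapiro(y).pvalue > 0.05
    )
    if normal:
        equal_var = stats.levene(x, y).pvalue > 0.05
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        test = "t-test" if equal_var else "welch-t"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann-whitney"
    summaries = {
        g: f"{v.mean():.2f} ± {v.std(ddof=1):.2f}" for g, v in ((g1, x), (g2, y))
    }
    return DemographicsEntry(var, test, float(res.statistic), float(res.pvalue), summaries)


def demographics(
    cohort: MorphometryCohort,
    continuous_vars: Sequence[str] = ("age",),
    categorical_vars: Sequence[str] = ("sex",),
) -> DemographicsReport:
    """Group-comparison statistics for demographic variables.

    Categorical variables get a Pearson chi-square (no continuity
    correction) on the group x level contingency table.  Continuous
    variables get a two-sample t-test when Shapiro-Wilk accepts normality in
    both groups (alpha = 0.05), otherwise a Mann-Whitney rank-sum test; the
    entry records which test was used.
    """
    entries: list[DemographicsEntry] = []
    for var in categorical_vars:
        if var not in cohort.subjects.columns:
            raise CohortValidationError(f"variable {var!r} missing from cohort")
        entries.append(_chi_square_entry(cohort, var))
    for var in continuous_vars:
        if var not in cohort.subjects.columns:
            raise CohortValidationError(f"variable {var!r} missing from cohort")
        entries.append(_continuous_entry(cohort, var))
    return DemographicsReport(entries=entries)


def aal90_regions() -> pd.DataFrame:
    """Lookup table for the 90 cortical/subcortical AAL regions.

    Returns a frame indexed 1..90 with ``name`` (descriptive region name)
    and ``abbreviation`` (conventional short label, e.g. ``TPOsup.L``).
    """
    ref = importlib.resources.files("scnkit") / "data" / "aal90.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", index_col="index")
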