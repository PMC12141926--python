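"""Cohort table I/O, validation and Table-1-style group summaries.

A cohort is one row per ICU stay: identifiers, 30-day survival outcome
(event indicator + censored time in days), a 48-h deterioration flag,
clinical covariates (SOFA, ventilation, age, sex, ethnicity, Elixhauser
index) and the 15-variable laboratory panel with missing values allowed.

Censoring convention: ``time_days = 30`` with ``event30 = 0`` is
administrative censoring at the 30-day horizon; deaths carry
``event30 = 1`` with ``time_days <= 30``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variables import VariableSpec, default_registry

__all__ = [
    "CohortTable",
    "ValidationIssue",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "group_summary",
    "MANDATORY_COLUMNS",
    "COVARIATE_COLUMNS",
]

MANDATORY_COLUMNS = ["patient_id", "time_days", "event30"]
COVARIATE_COLUMNS = [
    "deteriorated48",
    "sofa",
    "ventilated",
    "age",
    "sex",
    "ethnicity",
    "elixhauser",
]
CATEGORICAL_COLUMNS = {"sex", "ethnicity"}
FOLLOWUP_HORIZON_DAYS = 30.0

ETHNICITY_LEVELS = ["White", "Black", "Hispanic", "Asian", "Other", "Unknown"]


@dataclass
class CohortTable:
    """Patient-by-variable table plus its laboratory-variable registry."""

    registry: list[VariableSpec]
    df: pd.DataFrame

    @property
    def lab_names(self) -> list[str]:
        return [s.name for s in self.registry]

    @property
    def labs(self) -> pd.DataFrame:
        """The laboratory block as floats with NaN for missing."""
        return self.df[self.lab_names].astype(float)

    @property
    def n_patients(self) -> int:
        return len(self.df)

    def __post_init__(self):
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValueError(f"duplicate patient_id values: {dupes}")


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    field: str
    message: str


def _column_order(registry: Sequence[VariableSpec]) -> list[str]:
    return MANDATORY_COLUMNS + COVARIATE_COLUMNS + [s.name for s in registry]


def read_cohort(
    path: str | Path, registry: Sequence[VariableSpec] | None = None
) -> CohortTable:
    """Read a cohort CSV. Empty laboratory cells become missing (NaN).

    Raises ``ValueError`` on missing mandatory columns, non-numeric
    laboratory cells (named by row and column) and duplicate patient ids.
    """
    registry = list(registry) if registry is not None else default_registry()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    lab_names = [s.name for s in registry]

    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str)
    for col in ["time_days", "event30"] + [
        c for c in COVARIATE_COLUMNS if c in df.columns and c not in CATEGORICAL_COLUMNS
    ]:
        out[col] = _numeric_column(df, col, allow_missing=col not in MANDATORY_COLUMNS)
    for col in CATEGORICAL_COLUMNS:
        if col in df.columns:
            out[col] = df[col].replace("", np.nan)
    for col in lab_names:
        if col in df.columns:
            out[col] = _numeric_column(df, col, allow_missing=True)
        else:
            out[col] = np.nan
    # preserve original column order where possible
    ordered = [c for c in _column_order(registry) if c in out.columns]
    return CohortTable(registry, out[ordered].reset_index(drop=True))


def _numeric_column(df: pd.DataFrame, col: str, allow_missing: bool) -> pd.Series:
    # float() rather than pd.to_numeric: the latter's fast parser is not
    # correctly rounded, which would break bit-exact round-trips
    raw = df[col]
    values = np.empty(len(raw))
    for row, s in enumerate(raw):
        if s == "":
            if not allow_missing:
                raise ValueError(f"missing value in mandatory column {col!r}, row {row}")
            values[row] = np.nan
            continue
        try:
            values[row] = float(s)
        except ValueError:
            raise ValueError(
                f"non-numeric value {s!r} in column {col!r}, row {row}"
            ) from None
    return pd.Series(values, index=raw.index)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; missing values render as empty cells.

    Floats are rendered with shortest round-trip repr so that
    write -> read reproduces every value bit for bit.
    """
    cols = [c for c in _column_order(cohort.registry) if c in cohort.df.columns]
    out = cohort.df[cols].copy()
    for c in cols:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="")


def validate_cohort(cohort: CohortTable) -> list[ValidationIssue]:
    """Report (never fix) implausible values and outcome inconsistencies."""
    issues: list[ValidationIssue] = []
    df = cohort.df
    for spec in cohort.registry:
        if spec.plausibility_range is None or spec.name not in df.columns:
            continue
        lo, hi = spec.plausibility_range
        vals = df[spec.name].astype(float)
        bad = (vals < lo) | (vals > hi)
        for pid, v in zip(df.loc[bad, "patient_id"], vals[bad]):
            issues.append(
                ValidationIssue(
                    str(pid),
                    spec.name,
                    f"{spec.name}={v} outside plausible range [{lo}, {hi}]",
                )
            )
    over = df["time_days"].astype(float) > FOLLOWUP_HORIZON_DAYS
    for pid, t in zip(df.loc[over, "patient_id"], df.loc[over, "time_days"]):
        issues.append(
            ValidationIssue(str(pid), "time_days", f"time_days={t} exceeds 30-day horizon")
        )
    late_event = (df["event30"].astype(float) == 1) & (
        df["time_days"].astype(float) >= FOLLOWUP_HORIZON_DAYS
    )
    for pid in df.loc[late_event, "patient_id"]:
        issues.append(
            ValidationIssue(
                str(pid), "event30", "event30=1 with time_days >= 30 (event at/after horizon)"
            )
        )
    return issues


def group_summary(cohort: CohortTable, group_field: str = "event30") -> pd.DataFrame:
    """Median (Q1-Q3) per outcome group with Mann-Whitney / chi-squared p-values.

    Continuous variables (labs, age, SOFA, Elixhauser) are compared with the
    Mann-Whitney U test; categorical ones (sex, ethnicity levels, ventilation,
    the other outcome flag) with a chi-squared test without continuity
    correction. Quartiles use linear interpolation (numpy default, "type 7").
    """
    if group_field not in ("event30", "deteriorated48"):
        raise ValueError("group_field must be 'event30' or 'deteriorated48'")
    df = cohort.df
    g = df[group_field].astype(float)
    mask0, mask1 = g == 0, g == 1
    if mask0.sum() < 2 or mask1.sum() < 2:
        raise ValueError("each outcome group needs at least 2 members")

    continuous = [c for c in ("age", "sofa", "elixhauser") if c in df.columns]
    continuous += cohort.lab_names
    rows = []
    for col in continuous:
        vals = df[col].astype(float)
        a = vals[mask0].dropna().to_numpy()
        b = vals[mask1].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        if len(a) and len(b) and (np.ptp(np.concatenate([a, b])) == 0):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "variable": col,
                "kind": "continuous",
                "n0": len(a),
                "n1": len(b),
                "group0": _med_iqr(a),
                "group1": _med_iqr(b),
                "p": p,
            }
        )
    categorical = [c for c in ("ventilated", "sex") if c in df.columns]
    other_outcome = "deteriorated48" if group_field == "event30" else "event30"
    if other_outcome in df.columns:
        categorical.append(other_outcome)
    for col in categorical:
        sub = df[[col]].copy()
        sub["g"] = g
        sub = sub.dropna()
        tab = pd.crosstab(sub[col], sub["g"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])
        rows.append(
            {
                "variable": col,
                "kind": "categorical",
                "n0": int((sub["g"] == 0).sum()),
                "n1": int((sub["g"] == 1).sum()),
                "group0": _freq(sub.loc[sub["g"] == 0, col]),
                "group1": _freq(sub.loc[sub["g"] == 1, col]),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def chi_squared_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) for an r x c count table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def _med_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _freq(x: pd.Series) -> str:
    counts = x.value_counts().sort_index()
    return "; ".join(f"{k}: {v}" for k, v in counts.items())
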