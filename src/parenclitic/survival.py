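"""Evaluation battery for parenclitic deviations.

Mann-Whitney group comparisons with the rank-biserial-style effect size
r = |Z| / sqrt(N) (tie-corrected normal approximation, no continuity
correction -- the SPSS convention, which also makes AUC = U / (n0 * n1)
hold exactly); multivariate Cox proportional-hazards models on z-normalized
PDs (Efron ties, via lifelines); ROC analysis with DeLong confidence
intervals and Youden cut-offs; DeLong comparison of correlated AUCs; and
Kaplan-Meier curves with log-rank tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .cohort import CohortTable, ETHNICITY_LEVELS
from .deviation import PDMatrix, pd_column_name, z_normalize

__all__ = [
    "GroupComparison",
    "CoxResult",
    "CoxRow",
    "RocResult",
    "KMResult",
    "LogrankResult",
    "mann_whitney",
    "effect_size_from_u",
    "cox_fit",
    "roc_analysis",
    "delong_compare",
    "km_estimate",
    "logrank",
    "run_survival_pipeline",
    "write_report",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- Mann-Whitney


@dataclass(frozen=True)
class GroupComparison:
    n0: int
    n1: int
    mean0: float
    sd0: float
    mean1: float
    sd1: float
    U: float
    Z: float
    effect_r: float
    p: float


def mann_whitney(a: Sequence[float], b: Sequence[float], exact: bool = False) -> GroupComparison:
    """Compare a reference group ``a`` against a comparison group ``b``.

    U counts pairs where a comparison value exceeds a reference value (ties
    half), so U / (n0 * n1) is the probability a comparison-group draw beats
    a reference-group draw -- the empirical AUC. Z uses the tie-corrected
    normal approximation without continuity correction; ``exact`` switches
    the p-value to the exact U distribution (small samples, no ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n0, n1 = len(a), len(b)
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    rank_sum_b = ranks[n0:].sum()
    U = float(rank_sum_b - n1 * (n1 + 1) / 2.0)
    N = n0 + n1
    mu = n0 * n1 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var = n0 * n1 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        Z = 0.0
        p = 1.0
    else:
        Z = (U - mu) / np.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(Z)))
    if exact:
        p = float(stats.mannwhitneyu(b, a, alternative="two-sided", method="exact").pvalue)
    return GroupComparison(
        n0, n1,
        float(a.mean()), float(a.std(ddof=1)) if n0 > 1 else 0.0,
        float(b.mean()), float(b.std(ddof=1)) if n1 > 1 else 0.0,
        U, float(Z), float(abs(Z) / np.sqrt(N)), min(p, 1.0),
    )


def effect_size_from_u(U: float, n0: int, n1: int) -> float:
    """Effect size r = |Z| / sqrt(N) from a printed U and group sizes.

    Assumes no ties (continuous scores), the situation in which a published
    table reports U without tie structure.
    """
    N = n0 + n1
    mu = n0 * n1 / 2.0
    sd = np.sqrt(n0 * n1 * (N + 1) / 12.0)
    return float(abs(U - mu) / sd / np.sqrt(N))


# ------------------------------------------------------------------------ Cox


@dataclass(frozen=True)
class CoxRow:
    covariate: str
    beta: float
    se: float
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float


@dataclass
class CoxResult:
    rows: list[CoxRow]
    model_n: int
    events_n: int
    dropped_n: int

    def row(self, covariate: str) -> CoxRow:
        for r in self.rows:
            if r.covariate == covariate:
                return r
        raise KeyError(covariate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": [r.covariate for r in self.rows],
                "beta": [r.beta for r in self.rows],
                "se": [r.se for r in self.rows],
                "hazard_ratio": [r.hazard_ratio for r in self.rows],
                "hr_ci_low": [r.ci95[0] for r in self.rows],
                "hr_ci_high": [r.ci95[1] for r in self.rows],
                "p": [r.p for r in self.rows],
            }
        )


def cox_fit(
    time: Sequence[float],
    event: Sequence[float],
    covariates: pd.DataFrame,
    ties: str = "efron",
) -> CoxResult:
    """Multivariate proportional-hazards fit (partial likelihood, Efron ties).

    Rows with any missing covariate, time or event are dropped (complete
    case) and the count is reported. 95% CIs are exp(beta +/- 1.96 SE);
    p-values are Wald.
    """
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is provided")
    df = covariates.copy().astype(float)
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=float)
    n_all = len(df)
    df = df.dropna()
    dropped = n_all - len(df)
    if dropped:
        log.info("cox_fit: dropped %d incomplete rows of %d", dropped, n_all)
    if df["_event"].sum() < 1:
        raise ValueError("no events in the analysis sample")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    rows = []
    for name in covariates.columns:
        beta = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        rows.append(
            CoxRow(
                name, beta, se, float(np.exp(beta)),
                (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
                float(cph.summary.loc[name, "p"]),
            )
        )
    return CoxResult(rows, len(df), int(df["_event"].sum()), dropped)


# ------------------------------------------------------------------------ ROC


@dataclass
class RocResult:
    auc: float
    auc_ci95: tuple[float, float]
    auc_se: float
    youden_cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    flipped: bool = False  # True if scores were negated to orient AUC >= 0.5


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values for the DeLong variance machinery."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - rank_pos) / n  # P(neg < pos) per positive
    v01 = 1.0 - (ranks[m:] - rank_neg) / m  # per negative
    # same rank-sum expression as the Mann-Whitney U, so AUC == U/(m*n) exactly
    auc = float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return v10, v01, auc


def _auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    v10, v01, auc = _placements(pos, neg)
    m, n = len(pos), len(neg)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical AUC with DeLong 95% CI and the Youden-index cut-off.

    ``labels`` are 1 for the positive (poor-outcome) class. Scores are
    expected to run higher in the positive class; if the empirical AUC is
    below 0.5 the orientation is flipped automatically and flagged. The
    reported AUC equals U / (n0 * n1) of ``mann_whitney`` on the same data
    (identical rank computation). Classification rule at the cut-off:
    score >= cutoff predicts the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(y))
    s, y = s[ok], y[ok]
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc, _ = _auc_variance(pos, neg)
    flipped = False
    if auc < 0.5:
        log.info("roc_analysis: AUC %.3f < 0.5, flipping score orientation", auc)
        s = -s
        pos, neg = -pos, -neg
        flipped = True
    auc, var = _auc_variance(pos, neg)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    # Youden scan over observed cut-offs (predict positive when score >= c)
    cutoffs = np.unique(s)
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # ties: argmax takes the lowest cut-off
    return RocResult(
        auc, ci, se,
        float(cutoffs[best]) * (-1.0 if flipped else 1.0),
        float(j[best]), float(sens[best]), float(spec[best]),
        len(pos), len(neg), flipped,
    )


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    mode: str = "auto",
) -> tuple[float, float, float]:
    """DeLong test for a difference between two empirical AUCs.

    Paired mode works on the complete-case intersection (both scores
    observed) and uses the placement-value covariance; unpaired mode treats
    the AUCs as independent, each on its own complete cases. ``auto`` picks
    paired when the intersection has >= 10 patients of each class.
    Returns (delta_auc, z, two-sided p).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    both = ~(np.isnan(sa) | np.isnan(sb) | np.isnan(y))
    n_inter = int(both.sum())
    if mode == "auto":
        mode = "paired" if n_inter >= 10 else "unpaired"
        log.info("delong_compare: using %s mode (intersection n=%d)", mode, n_inter)
    if mode == "paired":
        if n_inter < 10:
            raise ValueError(
                f"paired DeLong needs >= 10 complete-case patients, have {n_inter}"
            )
        sa, sb, y = sa[both], sb[both], y[both]
        pos_mask, neg_mask = y == 1, y == 0
        v10a, v01a, auc_a = _placements(sa[pos_mask], sa[neg_mask])
        v10b, v01b, auc_b = _placements(sb[pos_mask], sb[neg_mask])
        m, n = int(pos_mask.sum()), int(neg_mask.sum())
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
        cov = s10 / m + s01 / n
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    else:
        oka = ~(np.isnan(sa) | np.isnan(y))
        okb = ~(np.isnan(sb) | np.isnan(y))
        auc_a, var_a = _auc_variance(sa[oka][y[oka] == 1], sa[oka][y[oka] == 0])
        auc_b, var_b = _auc_variance(sb[okb][y[okb] == 1], sb[okb][y[okb] == 0])
        var = var_a + var_b
    delta = float(auc_a - auc_b)
    if var <= 0:
        return delta, 0.0, 1.0
    z = delta / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return delta, float(z), min(p, 1.0)


# --------------------------------------------------------- KM and log-rank


@dataclass
class KMResult:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    survival_at_horizon: float


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float


def km_estimate(time: Sequence[float], event: Sequence[float], horizon: float = 30.0) -> KMResult:
    """Product-limit survival estimate with at-risk counts."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = table["at_risk"].to_numpy(dtype=float)
    censor_times = np.sort(t[e == 0])
    s30 = float(kmf.predict(horizon))
    return KMResult(times, surv, at_risk, censor_times, s30)


def logrank(time, event, group) -> LogrankResult:
    """Two-group log-rank test (1 df chi-squared)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(group)
    levels = pd.unique(g[~pd.isna(g)])
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {len(levels)}")
    m = g == levels[0]
    res = logrank_test(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


# ------------------------------------------------------------------- pipeline


STANDARD_COVARIATES = ["sofa", "ventilated"]
EXTENDED_COVARIATES = STANDARD_COVARIATES + ["age", "male", "elixhauser"]


def _design_columns(cohort: CohortTable, extended: bool) -> pd.DataFrame:
    df = cohort.df
    out = pd.DataFrame(index=df.index)
    out["sofa"] = df.get("sofa", np.nan)
    out["ventilated"] = df.get("ventilated", np.nan)
    if extended:
        out["age"] = df.get("age", np.nan)
        sex = df.get("sex")
        out["male"] = (sex.astype(str).str.upper().isin(["M", "MALE", "1"])).astype(float) if sex is not None else np.nan
        out["elixhauser"] = df.get("elixhauser", np.nan)
        eth = df.get("ethnicity")
        if eth is not None:
            # indicator contrasts against White
            for level in ETHNICITY_LEVELS[1:]:
                out[f"ethnicity_{level}"] = (eth == level).astype(float)
    return out


def run_survival_pipeline(
    cohort: CohortTable,
    pd_matrix: PDMatrix,
    outcome: str = "mortality30",
    cox_covariates: str = "standard",
    alpha: float = 0.05,
) -> dict:
    """Run the full evaluation chain over every PD edge.

    Stages per edge: Mann-Whitney group comparison; for edges with p < alpha
    a Cox model with covariates {PD(z), raw var_x, raw var_y, SOFA,
    ventilation} (extended adds age, male sex, Elixhauser and ethnicity
    contrasts); for Cox-significant PDs, ROC with Youden cut-off and a
    Kaplan-Meier + log-rank comparison of the predicted classes. Returns a
    JSON-serializable bundle.
    """
    if outcome == "mortality30":
        event = cohort.df["event30"].astype(float).to_numpy()
    elif outcome == "deterioration48":
        event = cohort.df["deteriorated48"].astype(float).to_numpy()
    else:
        raise ValueError("outcome must be 'mortality30' or 'deterioration48'")
    time = cohort.df["time_days"].astype(float).to_numpy()
    extended = cox_covariates == "extended"
    base_design = _design_columns(cohort, extended)
    labs = cohort.labs

    bundle: dict = {
        "outcome": outcome,
        "cox_covariates": cox_covariates,
        "alpha": alpha,
        "reference": pd_matrix.reference_label,
        "edges": {},
    }
    for (vx, vy), line in pd_matrix.lines.items():
        name = pd_column_name(vx, vy)
        entry: dict = {"var_x": vx, "var_y": vy, "n_fit": line.n_fit}
        pd_vals = pd_matrix.values[name].to_numpy(dtype=float)
        gc = mann_whitney(pd_vals[event == 0], pd_vals[event == 1])
        entry["group_comparison"] = vars(gc).copy()
        if gc.p < alpha:
            design = base_design.copy()
            design[name] = z_normalize(pd_vals)
            design[vx] = labs[vx].to_numpy()
            design[vy] = labs[vy].to_numpy()
            cols = [name, vx, vy] + [c for c in design.columns if c not in (name, vx, vy)]
            try:
                cox = cox_fit(time, event, design[cols])
            except Exception as err:  # convergence and data errors
                log.warning("cox stage failed for edge (%s, %s): %s", vx, vy, err)
                entry["cox_error"] = str(err)
                bundle["edges"][name] = entry
                continue
            entry["cox"] = {
                "model_n": cox.model_n,
                "events_n": cox.events_n,
                "dropped_n": cox.dropped_n,
                "rows": [vars(r).copy() for r in cox.rows],
            }
            pd_row = cox.row(name)
            if pd_row.p < alpha:
                roc = roc_analysis(pd_vals, event)
                entry["roc"] = vars(roc).copy()
                predicted_pos = pd_vals >= roc.youden_cutoff
                have = ~np.isnan(pd_vals)
                lr = logrank(time[have], event[have], predicted_pos[have])
                km_hi = km_estimate(time[have & predicted_pos], event[have & predicted_pos])
                km_lo = km_estimate(time[have & ~predicted_pos], event[have & ~predicted_pos])
                entry["km"] = {
                    "logrank_chi2": lr.chi2,
                    "logrank_p": lr.p,
                    "survival_at_30_beyond_cutoff": km_hi.survival_at_horizon,
                    "survival_at_30_below_cutoff": km_lo.survival_at_horizon,
                    "n_beyond": int((have & predicted_pos).sum()),
                    "n_below": int((have & ~predicted_pos).sum()),
                    "curve_beyond": _km_curve_dict(km_hi),
                    "curve_below": _km_curve_dict(km_lo),
                }
        bundle["edges"][name] = entry
    return bundle


def _km_curve_dict(km: KMResult) -> dict:
    return {
        "times": [float(v) for v in km.times],
        "survival": [float(v) for v in km.survival],
        "at_risk": [float(v) for v in km.at_risk],
    }


def write_report(bundle: dict, outdir: str | Path) -> list[Path]:
    """Emit the machine-readable report: JSON bundle + per-table CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _dump(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)

    rows = []
    for name, entry in bundle["edges"].items():
        gc = entry["group_comparison"]
        rows.append({"edge": name, **gc})
    _dump(pd.DataFrame(rows), "table2_group_comparison.csv")

    cox_rows = []
    for name, entry in bundle["edges"].items():
        for r in entry.get("cox", {}).get("rows", []):
            cox_rows.append({"edge": name, **{k: (list(v) if isinstance(v, tuple) else v) for k, v in r.items()}})
    cdf = pd.DataFrame(cox_rows)
    if not cdf.empty and "ci95" in cdf.columns:
        cdf["hr_ci_low"] = cdf["ci95"].str[0]
        cdf["hr_ci_high"] = cdf["ci95"].str[1]
        cdf = cdf.drop(columns=["ci95"])
    _dump(cdf, "table4_cox.csv")

    roc_rows = []
    km_rows = []
    for name, entry in bundle["edges"].items():
        if "roc" in entry:
            r = entry["roc"].copy()
            r["auc_ci_low"], r["auc_ci_high"] = r.pop("auc_ci95")
            roc_rows.append({"edge": name, **r})
        if "km" in entry:
            for arm in ("beyond", "below"):
                curve = entry["km"][f"curve_{arm}"]
                for t, s, n in zip(curve["times"], curve["survival"], curve["at_risk"]):
                    km_rows.append({"edge": name, "arm": arm, "time": t, "survival": s, "at_risk": n})
    _dump(pd.DataFrame(roc_rows), "table6_roc.csv")
    _dump(pd.DataFrame(km_rows), "km_curves.csv")

    jp = outdir / "report.json"
    jp.write_text(json.dumps(bundle, indent=2, sort_keys=True, default=_json_default))
    written.append(jp)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
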