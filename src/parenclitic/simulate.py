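"""Synthetic ICU sepsis cohorts with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two latent outcome groups (survivor-like and non-survivor-like)
with group-specific mean vectors and correlation matrices over the
15-variable laboratory panel, MCAR missingness per variable, and 30-day
survival times whose hazard rises with the patient's orthogonal deviation
from a planted acid-base axis (arterial pH vs bicarbonate).

Every draw flows from a single seed, and the planted truth (line, hazard
coefficient, per-patient deviations, uncensored event times) is returned so
each pipeline stage can be tested for recovery without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import CohortTable, ETHNICITY_LEVELS
from .variables import default_registry

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "default_config",
    "generate_cohort",
    "truth_report",
    "load_truth",
    "load_config",
    "save_config",
]

VAR_NAMES = [s.name for s in default_registry()]
_IQR_TO_SD = 2 * stats.norm.ppf(0.75)  # ~1.349: IQR of a normal in SD units

# Group-level location/scale for each lab, survivor-like vs non-survivor-like.
# Medians and IQR-derived SDs follow the direction of published ICU sepsis
# contrasts: the poor-outcome group runs higher in lactate, urea, creatinine,
# phosphate, WBC, glucose, INR and lower in pH and bicarbonate.
_SURVIVOR_STATS = {  # name: (median, iqr)
    "phosphate": (3.1, 1.3), "arterial_ph": (7.39, 0.07), "urea": (16.5, 12.8),
    "hemoglobin": (11.2, 2.5), "lactate": (1.6, 1.2), "wbc": (10.8, 5.8),
    "sodium": (139.0, 4.2), "inr": (1.2, 0.3), "platelets": (217.0, 118.5),
    "bilirubin": (0.6, 1.2), "glucose": (124.5, 41.6), "creatinine": (0.9, 0.5),
    "alt": (28.0, 42.5), "bicarbonate": (24.0, 4.0), "potassium": (4.2, 0.9),
}
_NONSURVIVOR_STATS = {
    "phosphate": (3.9, 1.6), "arterial_ph": (7.32, 0.22), "urea": (23.3, 20.9),
    "hemoglobin": (11.7, 2.1), "lactate": (3.8, 4.6), "wbc": (13.0, 6.4),
    "sodium": (139.0, 6.9), "inr": (1.3, 0.6), "platelets": (187.3, 148.5),
    "bilirubin": (0.68, 0.72), "glucose": (143.6, 59.5), "creatinine": (1.1, 0.8),
    "alt": (30.0, 132.3), "bicarbonate": (22.0, 10.2), "potassium": (3.9, 1.6),
}

# Planted correlation edges per group, |r| in the 0.5-0.8 band, signs
# physiological (lactate acidifies: negative with pH and bicarbonate).
SURVIVOR_EDGES = {
    ("wbc", "platelets"): 0.55,
    ("inr", "alt"): 0.55,
    ("arterial_ph", "bicarbonate"): 0.75,
    ("urea", "creatinine"): 0.75,
}
NONSURVIVOR_EDGES = {
    ("wbc", "phosphate"): 0.65,
    ("lactate", "arterial_ph"): -0.65,
    ("lactate", "bicarbonate"): -0.60,
    ("urea", "creatinine"): 0.80,
}

# MCAR missingness per variable, calibrated so the headline pairwise
# complete-case fractions resemble a cohort in which arterial blood gas
# values (pH, lactate) are often absent: pH & bicarbonate jointly observed
# in ~57% of patients.
_MISSING_PROB = {
    "phosphate": 0.07, "arterial_ph": 0.42, "urea": 0.01, "hemoglobin": 0.01,
    "lactate": 0.30, "wbc": 0.02, "sodium": 0.01, "inr": 0.10,
    "platelets": 0.02, "bilirubin": 0.10, "glucose": 0.02, "creatinine": 0.01,
    "alt": 0.12, "bicarbonate": 0.01, "potassium": 0.01,
}


@dataclass
class SyntheticConfig:
    n_patients: int = 162
    mortality_fraction: float = 33 / 162
    deterioration_fraction: float = 30 / 162
    mean_survivor: np.ndarray = None
    mean_nonsurvivor: np.ndarray = None
    sd_survivor: np.ndarray = None
    sd_nonsurvivor: np.ndarray = None
    corr_survivor: np.ndarray = None
    corr_nonsurvivor: np.ndarray = None
    missing_prob: np.ndarray = None
    lambda0: float = 0.006  # baseline daily hazard; recalibrated in default_config
    beta_pd: float = 0.733  # log-HR per SD of the planted deviation
    beta_sofa: float = 0.0
    beta_vent: float = 0.0
    horizon_days: float = 30.0
    planted_edge: tuple[str, str] = ("arterial_ph", "bicarbonate")
    deterioration_slope: float = 1.0
    deterioration_intercept: float = -1.5  # recalibrated in default_config
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    missing_group_multiplier: float = 1.0  # >1 makes the poor-outcome group sparser (MAR hook)
    seed: int = 0

    def variable_index(self, name: str) -> int:
        return VAR_NAMES.index(name)


@dataclass
class TruthRecord:
    patients: pd.DataFrame  # patient_id, group, true_deviation, uncensored_time
    planted_centroid: tuple[float, float]
    planted_direction: tuple[float, float]
    beta_pd: float
    deviation_mean: float
    deviation_sd: float
    corr_survivor: np.ndarray
    corr_nonsurvivor: np.ndarray
    seed: int


def _corr_matrix(edges: dict) -> np.ndarray:
    m = len(VAR_NAMES)
    C = np.eye(m)
    for (a, b), r in edges.items():
        i, j = VAR_NAMES.index(a), VAR_NAMES.index(b)
        C[i, j] = C[j, i] = r
    return _nearest_pd(C)


def _nearest_pd(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest positive-definite correlation."""
    evals, evecs = np.linalg.eigh(C)
    if evals.min() > floor:
        return C
    evals = np.clip(evals, floor, None)
    repaired = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _planted_line(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of the survivor-group covariance of the planted pair."""
    i = cfg.variable_index(cfg.planted_edge[0])
    j = cfg.variable_index(cfg.planted_edge[1])
    sx, sy = cfg.sd_survivor[i], cfg.sd_survivor[j]
    r = cfg.corr_survivor[i, j]
    cov = np.array([[sx**2, r * sx * sy], [r * sx * sy, sy**2]])
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, 1]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    centroid = np.array([cfg.mean_survivor[i], cfg.mean_survivor[j]])
    return centroid, direction


def _deviation_params(cfg: SyntheticConfig) -> tuple[float, float, list[tuple[float, float, float]]]:
    """Population mean/SD of the planted deviation (folded-normal mixture).

    The signed offset of a group-g patient along the planted line's normal is
    Gaussian with closed-form mean and variance, so the deviation |offset| is
    folded normal and the mixture moments are exact.
    """
    centroid, direction = _planted_line(cfg)
    normal = np.array([-direction[1], direction[0]])
    i = cfg.variable_index(cfg.planted_edge[0])
    j = cfg.variable_index(cfg.planted_edge[1])
    comps = []
    for mean, sd, corr, w in (
        (cfg.mean_survivor, cfg.sd_survivor, cfg.corr_survivor, 1 - cfg.mortality_fraction),
        (cfg.mean_nonsurvivor, cfg.sd_nonsurvivor, cfg.corr_nonsurvivor, cfg.mortality_fraction),
    ):
        mu2 = np.array([mean[i], mean[j]]) - centroid
        cov = np.array(
            [
                [sd[i] ** 2, corr[i, j] * sd[i] * sd[j]],
                [corr[i, j] * sd[i] * sd[j], sd[j] ** 2],
            ]
        )
        m = float(normal @ mu2)
        v = float(normal @ cov @ normal)
        comps.append((w, m, np.sqrt(v)))
    mean_d = 0.0
    mean_d2 = 0.0
    for w, m, s in comps:
        # folded normal moments
        e1 = s * np.sqrt(2 / np.pi) * np.exp(-(m**2) / (2 * s**2)) + m * (
            1 - 2 * stats.norm.cdf(-m / s)
        )
        e2 = m**2 + s**2
        mean_d += w * e1
        mean_d2 += w * e2
    sd_d = float(np.sqrt(mean_d2 - mean_d**2))
    return float(mean_d), sd_d, comps


def _death_probability(lambda0: float, cfg, mu_d, sd_d, comps) -> float:
    """Marginal P(event before horizon) under the mixture, by quadrature."""
    total = 0.0
    for w, m, s in comps:
        grid = np.linspace(m - 8 * s, m + 8 * s, 4001)
        dens = stats.norm.pdf(grid, m, s)
        z = (np.abs(grid) - mu_d) / sd_d
        p_death = 1.0 - np.exp(-cfg.horizon_days * lambda0 * np.exp(cfg.beta_pd * z))
        total += w * np.trapezoid(dens * p_death, grid)
    return float(total)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Documented defaults: 162 patients, ~20% 30-day mortality, planted
    pH-bicarbonate axis with log-HR 0.733 per SD of deviation.

    The baseline hazard and the deterioration intercept are calibrated
    deterministically (closed-form folded-normal quadrature) so expected
    event fractions match the configured ones.
    """
    means_s = np.array([_SURVIVOR_STATS[v][0] for v in VAR_NAMES])
    means_n = np.array([_NONSURVIVOR_STATS[v][0] for v in VAR_NAMES])
    sds_s = np.array([_SURVIVOR_STATS[v][1] / _IQR_TO_SD for v in VAR_NAMES])
    sds_n = np.array([_NONSURVIVOR_STATS[v][1] / _IQR_TO_SD for v in VAR_NAMES])
    cfg = SyntheticConfig(
        mean_survivor=means_s,
        mean_nonsurvivor=means_n,
        sd_survivor=sds_s,
        sd_nonsurvivor=sds_n,
        corr_survivor=_corr_matrix(SURVIVOR_EDGES),
        corr_nonsurvivor=_corr_matrix(NONSURVIVOR_EDGES),
        missing_prob=np.array([_MISSING_PROB[v] for v in VAR_NAMES]),
        seed=seed,
    )
    mu_d, sd_d, comps = _deviation_params(cfg)
    target = cfg.mortality_fraction
    lo, hi = 1e-6, 1.0
    cfg.lambda0 = float(
        optimize.brentq(
            lambda lam: _death_probability(lam, cfg, mu_d, sd_d, comps) - target, lo, hi
        )
    )
    # deterioration intercept: E[sigmoid(a + slope*z)] = deterioration_fraction
    def det_frac(a):
        total = 0.0
        for w, m, s in comps:
            grid = np.linspace(m - 8 * s, m + 8 * s, 4001)
            dens = stats.norm.pdf(grid, m, s)
            z = (np.abs(grid) - mu_d) / sd_d
            total += w * np.trapezoid(
                dens / (1.0 + np.exp(-(a + cfg.deterioration_slope * z))), grid
            )
        return total
    cfg.deterioration_intercept = float(
        optimize.brentq(lambda a: det_frac(a) - cfg.deterioration_fraction, -20, 20)
    )
    return cfg


def generate_cohort(config: SyntheticConfig) -> tuple[CohortTable, TruthRecord]:
    """Draw a cohort and its planted truth; identical (config, seed) in,
    identical output out."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    registry = default_registry()
    bounds = {s.name: s.plausibility_range for s in registry}

    group = rng.random(n) < cfg.mortality_fraction  # True = non-survivor-like
    labs = np.empty((n, len(VAR_NAMES)))
    for is_ns, mean, sd, corr in (
        (False, cfg.mean_survivor, cfg.sd_survivor, cfg.corr_survivor),
        (True, cfg.mean_nonsurvivor, cfg.sd_nonsurvivor, cfg.corr_nonsurvivor),
    ):
        rows = np.flatnonzero(group == is_ns)
        if len(rows) == 0:
            continue
        cov = corr * np.outer(sd, sd)
        cov = (cov + cov.T) / 2
        labs[rows] = rng.multivariate_normal(mean, cov, size=len(rows), method="cholesky")
    # truncate strictly-positive analytes at plausibility bounds (keeps the
    # linear correlation structure; clipping is rare with these scales)
    for k, name in enumerate(VAR_NAMES):
        lo, hi = bounds[name]
        labs[:, k] = np.clip(labs[:, k], lo, hi)

    centroid, direction = _planted_line(cfg)
    normal = np.array([-direction[1], direction[0]])
    i = cfg.variable_index(cfg.planted_edge[0])
    j = cfg.variable_index(cfg.planted_edge[1])
    deviation = np.abs((labs[:, [i, j]] - centroid) @ normal)
    mu_d, sd_d, _ = _deviation_params(cfg)
    z = (deviation - mu_d) / sd_d

    sofa = np.where(
        group,
        np.round(rng.normal(7.0, 4.5, n)),
        np.round(rng.normal(4.0, 2.5, n)),
    )
    sofa = np.clip(sofa, 0, 24).astype(int)
    ventilated = (rng.random(n) < np.where(group, 0.55, 0.21)).astype(int)
    age = np.clip(np.where(group, rng.normal(76, 13, n), rng.normal(66, 15, n)), 18, 100)
    male = rng.random(n) < np.where(group, 0.70, 0.55)
    eth_probs_s = np.array([0.783, 0.054, 0.023, 0.023, 0.023, 0.094])
    eth_probs_n = np.array([0.667, 0.091, 0.061, 0.0, 0.0, 0.181])
    eth_probs_s = eth_probs_s / eth_probs_s.sum()
    eth_probs_n = eth_probs_n / eth_probs_n.sum()
    eth_idx = np.array(
        [
            rng.choice(6, p=eth_probs_n if g else eth_probs_s)
            for g in group
        ]
    )
    ethnicity = np.array(ETHNICITY_LEVELS)[eth_idx]
    elixhauser = np.clip(
        np.round(np.where(group, rng.normal(24, 6.3, n), rng.normal(22, 4.4, n))), 0, 60
    ).astype(int)

    log_rate = (
        np.log(cfg.lambda0)
        + cfg.beta_pd * z
        + cfg.beta_sofa * sofa
        + cfg.beta_vent * ventilated
    )
    rate = np.exp(log_rate)
    if cfg.weibull_shape == 1.0:
        uncensored = rng.exponential(1.0 / rate)
    else:
        # Weibull with proportional hazards: S(t) = exp(-(rate) * t^shape)
        u = rng.random(n)
        uncensored = (-np.log(u) / rate) ** (1.0 / cfg.weibull_shape)
    event30 = (uncensored < cfg.horizon_days).astype(int)
    time_days = np.minimum(uncensored, cfg.horizon_days)

    p_det = 1.0 / (
        1.0 + np.exp(-(cfg.deterioration_intercept + cfg.deterioration_slope * z))
    )
    deteriorated = (rng.random(n) < p_det).astype(int)

    miss = cfg.missing_prob.copy()
    lab_obs = labs.copy()
    for k in range(len(VAR_NAMES)):
        p_miss = np.where(
            group, min(miss[k] * cfg.missing_group_multiplier, 0.95), miss[k]
        )
        lab_obs[rng.random(n) < p_miss, k] = np.nan

    pid = np.array([f"P{idx:04d}" for idx in range(n)])
    df = pd.DataFrame(
        {
            "patient_id": pid,
            "time_days": np.round(time_days, 6),
            "event30": event30,
            "deteriorated48": deteriorated,
            "sofa": sofa,
            "ventilated": ventilated,
            "age": np.round(age, 1),
            "sex": np.where(male, "M", "F"),
            "ethnicity": ethnicity,
            "elixhauser": elixhauser,
        }
    )
    for k, name in enumerate(VAR_NAMES):
        df[name] = lab_obs[:, k]
    cohort = CohortTable(registry, df)
    truth = TruthRecord(
        pd.DataFrame(
            {
                "patient_id": pid,
                "group": np.where(group, "nonsurvivor", "survivor"),
                "true_deviation": deviation,
                "uncensored_time": uncensored,
            }
        ),
        (float(centroid[0]), float(centroid[1])),
        (float(direction[0]), float(direction[1])),
        cfg.beta_pd,
        mu_d,
        sd_d,
        cfg.corr_survivor,
        cfg.corr_nonsurvivor,
        cfg.seed,
    )
    return cohort, truth


def truth_report(truth: TruthRecord, path: str | Path) -> None:
    """Serialize the planted ground truth as JSON (lossless round-trip)."""
    payload = {
        "planted_centroid": list(truth.planted_centroid),
        "planted_direction": list(truth.planted_direction),
        "beta_pd": truth.beta_pd,
        "deviation_mean": truth.deviation_mean,
        "deviation_sd": truth.deviation_sd,
        "seed": truth.seed,
        "corr_survivor": truth.corr_survivor.tolist(),
        "corr_nonsurvivor": truth.corr_nonsurvivor.tolist(),
        "patients": truth.patients.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_truth(path: str | Path) -> TruthRecord:
    d = json.loads(Path(path).read_text())
    return TruthRecord(
        pd.DataFrame(d["patients"]),
        tuple(d["planted_centroid"]),
        tuple(d["planted_direction"]),
        float(d["beta_pd"]),
        float(d["deviation_mean"]),
        float(d["deviation_sd"]),
        np.array(d["corr_survivor"]),
        np.array(d["corr_nonsurvivor"]),
        int(d["seed"]),
    )


_ARRAY_FIELDS = [
    "mean_survivor", "mean_nonsurvivor", "sd_survivor", "sd_nonsurvivor",
    "corr_survivor", "corr_nonsurvivor", "missing_prob",
]


def save_config(cfg: SyntheticConfig, path: str | Path) -> None:
    d = {k: v for k, v in vars(cfg).items()}
    for k in _ARRAY_FIELDS:
        d[k] = np.asarray(d[k]).tolist()
    d["planted_edge"] = list(d["planted_edge"])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> SyntheticConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for k in _ARRAY_FIELDS:
        d[k] = np.asarray(d[k], dtype=float)
    d["planted_edge"] = tuple(d["planted_edge"])
    return SyntheticConfig(**d)
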