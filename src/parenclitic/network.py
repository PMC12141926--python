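"""Population correlation network maps.

Nodes are laboratory variables; an edge joins two variables whose Pearson
correlation within one outcome group survives a Bonferroni gate over all
C(m, 2) pairs. Correlations use pairwise deletion ("pair matching"): a
patient contributes to a pair only when both variables are observed.
P-values are parametric, from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2
degrees of freedom; a rank-based (Spearman) alternative is available as an
option but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "EdgeStat",
    "CorrelationNetwork",
    "bonferroni_threshold",
    "pairwise_pearson",
    "pairwise_pearson_matrix",
    "build_network",
    "compare_networks",
    "export_network",
    "load_network_graphml",
    "GROUP_SELECTORS",
]

log = logging.getLogger(__name__)

LOW_N_FLAG_THRESHOLD = 10  # edges evaluated on fewer pairs carry a low-n flag

# Named subgroup selectors for the two outcomes and their complements.
GROUP_SELECTORS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "survived30": lambda df: df["event30"].astype(float) == 0,
    "died30": lambda df: df["event30"].astype(float) == 1,
    "deteriorated48": lambda df: df["deteriorated48"].astype(float) == 1,
    "stable48": lambda df: df["deteriorated48"].astype(float) == 0,
}


@dataclass(frozen=True)
class EdgeStat:
    """Pearson statistics for one unordered variable pair."""

    var_x: str
    var_y: str
    r: float
    p: float
    n_pairs: int
    significant: bool
    low_n: bool = False
    reason: str | None = None  # set when the pair could not be evaluated

    @property
    def pair(self) -> frozenset:
        return frozenset((self.var_x, self.var_y))


@dataclass
class CorrelationNetwork:
    variables: list[str]
    edges: list[EdgeStat]
    adjacency: np.ndarray
    threshold: float
    group_label: str
    alpha: float = 0.05

    def significant_edges(self) -> list[EdgeStat]:
        return [e for e in self.edges if e.significant]

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "var_x": [e.var_x for e in self.edges],
                "var_y": [e.var_y for e in self.edges],
                "r": [e.r for e in self.edges],
                "p": [e.p for e in self.edges],
                "n_pairs": [e.n_pairs for e in self.edges],
                "significant": [int(e.significant) for e in self.edges],
                "low_n": [int(e.low_n) for e in self.edges],
            }
        )


def bonferroni_threshold(m_variables: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / C(m, 2) over all variable pairs."""
    if m_variables < 2:
        raise ValueError("need at least 2 variables")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / comb(m_variables, 2)


def pairwise_pearson(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float, int]:
    """Pearson r, two-sided t-test p and complete-pair count, pairwise deletion.

    Missing values are NaN. Perfect correlation |r| = 1 returns p = 0
    (the boundary convention of the t statistic).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"insufficient pairs: {n} complete pairs (need >= 3)")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variable: zero variance on complete pairs")
    r, p = _pearson_t(x, y, n)
    return r, p, n


def _pearson_t(x: np.ndarray, y: np.ndarray, n: int) -> tuple[float, float]:
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p


def pairwise_pearson_matrix(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson with pairwise deletion, vectorized.

    Parameters: X of shape (n_samples, m_variables), NaN = missing.
    Returns (R, P, N): m x m matrices of correlations, two-sided p-values and
    complete-pair counts. Pairs with fewer than 3 complete cases or zero
    variance get NaN in R and P. Diagonals are r = 1, p = 0.
    """
    X = np.asarray(X, dtype=float)
    mask = ~np.isnan(X)
    Z = np.where(mask, X, 0.0)
    M = mask.astype(float)
    N = M.T @ M
    Sx = Z.T @ M  # Sx[i, j] = sum of x_i over rows where both i and j observed
    Sxx = (Z * Z).T @ M
    Sxy = Z.T @ Z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        varx = N * Sxx - Sx**2
        vary = varx.T
        denom = np.sqrt(varx * vary)
        R = cov / denom
    R = np.clip(R, -1.0, 1.0)
    bad = (N < 3) | (varx <= 0) | (vary <= 0)
    R[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        T = R * np.sqrt((N - 2) / (1.0 - R**2))
    P = 2.0 * stats.t.sf(np.abs(T), np.maximum(N - 2, 1))
    P[np.abs(R) == 1.0] = 0.0
    P[bad] = np.nan
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    return R, P, N.astype(int)


def build_network(
    cohort: CohortTable,
    group_selector: str | Callable[[pd.DataFrame], pd.Series] | np.ndarray,
    alpha: float = 0.05,
    method: str = "pearson",
) -> CorrelationNetwork:
    """Correlation network map for one outcome subgroup.

    ``group_selector`` is a named group ("survived30", "died30",
    "deteriorated48", "stable48"), a boolean mask, or a callable mapping the
    cohort frame to a boolean mask. Pairs that cannot be evaluated
    (insufficient complete pairs, zero variance) are recorded as
    non-significant with a logged reason rather than dropped.
    """
    label, mask = _resolve_selector(cohort, group_selector)
    sub = cohort.df.loc[mask]
    if len(sub) == 0:
        raise ValueError(f"empty subgroup for selector {label!r}")
    names = cohort.lab_names
    m = len(names)
    X = sub[names].astype(float).to_numpy()
    if method == "pearson":
        R, P, N = pairwise_pearson_matrix(X)
    elif method == "spearman":
        R, P, N = _spearman_matrix(X)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    threshold = bonferroni_threshold(m, alpha)
    edges: list[EdgeStat] = []
    adjacency = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            r, p, n = R[i, j], P[i, j], int(N[i, j])
            if np.isnan(r):
                reason = "insufficient pairs" if n < 3 else "degenerate variable"
                log.info(
                    "pair (%s, %s) in group %s not evaluable: %s (n=%d)",
                    names[i], names[j], label, reason, n,
                )
                edges.append(
                    EdgeStat(names[i], names[j], np.nan, np.nan, n, False, n < 10, reason)
                )
                continue
            sig = bool(p <= threshold)
            edges.append(
                EdgeStat(names[i], names[j], float(r), float(p), n, sig,
                         n < LOW_N_FLAG_THRESHOLD)
            )
            if sig:
                adjacency[i, j] = adjacency[j, i] = 1
    return CorrelationNetwork(list(names), edges, adjacency, threshold, label, alpha)


def _resolve_selector(cohort, selector):
    if isinstance(selector, str):
        if selector not in GROUP_SELECTORS:
            raise ValueError(f"unknown group {selector!r}")
        return selector, GROUP_SELECTORS[selector](cohort.df).to_numpy()
    if callable(selector):
        mask = selector(cohort.df)
        return getattr(selector, "__name__", "custom"), np.asarray(mask, dtype=bool)
    return "custom", np.asarray(selector, dtype=bool)


def _spearman_matrix(X):
    ranked = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        ok = ~np.isnan(X[:, j])
        ranked[ok, j] = stats.rankdata(X[ok, j])
    # ranks must be recomputed per pair under pairwise deletion; fall back to loops
    m = X.shape[1]
    R = np.full((m, m), np.nan)
    P = np.full((m, m), np.nan)
    N = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            ok = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            n = int(ok.sum())
            N[i, j] = N[j, i] = n
            if n < 3:
                continue
            xi = stats.rankdata(X[ok, i])
            yj = stats.rankdata(X[ok, j])
            if np.ptp(xi) == 0 or np.ptp(yj) == 0:
                continue
            r, p = _pearson_t(xi, yj, n)
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(P, 0.0)
    return R, P, N


def compare_networks(
    a: CorrelationNetwork, b: CorrelationNetwork
) -> tuple[set, set, set]:
    """Partition significant edges into (shared, unique-to-a, unique-to-b)."""
    if a.variables != b.variables:
        raise ValueError("networks are over different variable lists")
    ea = {e.pair for e in a.significant_edges()}
    eb = {e.pair for e in b.significant_edges()}
    return ea & eb, ea - eb, eb - ea


def export_network(net: CorrelationNetwork, path: str | Path) -> None:
    """Write GraphML plus a CSV edge list (all pairs, significance flagged).

    ``path`` is a prefix: writes ``<path>.graphml`` and ``<path>_edges.csv``.
    Edge weight is |r|; the sign of r is kept as a separate attribute.
    """
    path = Path(path)
    g = nx.Graph(group=net.group_label, threshold=float(net.threshold),
                 alpha=float(net.alpha))
    for v in net.variables:
        g.add_node(v)
    for e in net.significant_edges():
        g.add_edge(
            e.var_x, e.var_y,
            r=float(e.r), p=float(e.p), n_pairs=int(e.n_pairs),
            weight=float(abs(e.r)), sign=int(np.sign(e.r)),
            significant=True, low_n=bool(e.low_n),
        )
    nx.write_graphml(g, path.with_suffix(".graphml"))
    net.edge_table().to_csv(path.parent / (path.name + "_edges.csv"), index=False)


def load_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
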