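"""Parenclitic deviations: orthogonal regression on a reference population.

For each significant variable pair, a total-least-squares (orthogonal) line
is fit on the reference population (survivors for the 30-day outcome,
non-deteriorated patients for 48-h deterioration). A patient's parenclitic
deviation (PD) on that pair is the Euclidean distance from their data point
to the line: how far their physiology departs from the reference coupling.

The TLS line is the first principal axis of the 2-variable covariance, which
is symmetric in the two variables and well defined for vertical lines.
Variables enter in raw units with no pre-standardization, so PD magnitudes
track the raw scales of the pair. PD is unsigned; the signed orthogonal
residual is available as a diagnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ReferenceLine",
    "PDMatrix",
    "fit_orthogonal_line",
    "orthogonal_distance",
    "signed_orthogonal_residual",
    "compute_pd_matrix",
    "z_normalize",
    "write_pd_matrix",
    "read_pd_matrix",
    "pd_column_name",
]

log = logging.getLogger(__name__)

DEGENERATE_EIGENGAP = 1e-12


@dataclass(frozen=True)
class ReferenceLine:
    """Orthogonal-regression line: centroid + unit direction, raw units."""

    var_x: str
    var_y: str
    centroid: tuple[float, float]
    direction: tuple[float, float]  # unit vector along the line
    n_fit: int
    orthogonal_sse: float

    @property
    def normal(self) -> tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)

    @property
    def slope_intercept(self) -> tuple[float, float] | None:
        """(slope, intercept) in y = a*x + b form; None for vertical lines."""
        dx, dy = self.direction
        if dx == 0:
            return None
        a = dy / dx
        cx, cy = self.centroid
        return a, cy - a * cx


def fit_orthogonal_line(
    points: Sequence[tuple[float, float]] | np.ndarray,
    var_x: str = "x",
    var_y: str = "y",
) -> ReferenceLine:
    """Fit the line minimizing summed squared orthogonal distances.

    The minimizer is the principal eigenvector of the 2x2 covariance of the
    points, through their centroid; the residual SSE equals the smaller
    eigenvalue times (n - 1). An isotropic cloud (equal eigenvalues) has no
    preferred axis and raises.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if np.isnan(pts).any():
        raise ValueError("points must be complete (no NaN)")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points to fit a line, got {n}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    scale = max(evals[1], 1.0)
    if evals[1] - evals[0] <= DEGENERATE_EIGENGAP * scale:
        raise ValueError("direction ambiguous: isotropic or degenerate point cloud")
    direction = evecs[:, 1]
    # deterministic orientation: positive x-component (positive y if vertical)
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    sse = float(evals[0] * (n - 1))
    return ReferenceLine(
        var_x,
        var_y,
        (float(centroid[0]), float(centroid[1])),
        (float(direction[0]), float(direction[1])),
        n,
        max(sse, 0.0),
    )


def signed_orthogonal_residual(point, line: ReferenceLine) -> float:
    """Signed offset of a point along the line's normal (diagnostic output)."""
    px, py = float(point[0]), float(point[1])
    cx, cy = line.centroid
    nx_, ny_ = line.normal
    return (px - cx) * nx_ + (py - cy) * ny_


def orthogonal_distance(point, line: ReferenceLine) -> float:
    """Euclidean distance from a point to the infinite reference line."""
    return abs(signed_orthogonal_residual(point, line))


def pd_column_name(var_x: str, var_y: str) -> str:
    return f"PD__{var_x}__{var_y}"


@dataclass
class PDMatrix:
    """Patients x edges matrix of non-negative parenclitic deviations.

    ``values`` is indexed by patient_id with one ``PD__x__y`` column per
    edge; an entry is NaN exactly when the patient lacks either variable.
    """

    values: pd.DataFrame
    lines: dict[tuple[str, str], ReferenceLine]
    reference_label: str

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.lines.keys())

    def column(self, var_x: str, var_y: str) -> pd.Series:
        return self.values[pd_column_name(var_x, var_y)]


def compute_pd_matrix(
    cohort: CohortTable,
    reference_selector,
    edges: Sequence[tuple[str, str]],
    leave_one_out: bool = False,
) -> PDMatrix:
    """Fit one reference line per edge and score every patient against it.

    The line for each edge is fit on the reference subgroup's complete pairs
    (raw units). Every patient in the whole cohort with both values present
    gets a PD; edges with fewer than 3 reference pairs are omitted with a
    logged reason. Reference members are scored against a line that includes
    themselves unless ``leave_one_out`` is set (sensitivity mode).
    """
    from .network import _resolve_selector  # shared selector semantics

    label, mask = _resolve_selector(cohort, reference_selector)
    df = cohort.df
    labs = cohort.labs
    values = pd.DataFrame(index=df["patient_id"].astype(str))
    lines: dict[tuple[str, str], ReferenceLine] = {}
    for var_x, var_y in edges:
        x = labs[var_x].to_numpy()
        y = labs[var_y].to_numpy()
        ref_ok = mask & ~np.isnan(x) & ~np.isnan(y)
        pts = np.column_stack([x[ref_ok], y[ref_ok]])
        if pts.shape[0] < 3:
            log.warning(
                "edge (%s, %s) omitted: only %d complete reference pairs",
                var_x, var_y, pts.shape[0],
            )
            continue
        try:
            line = fit_orthogonal_line(pts, var_x, var_y)
        except ValueError as err:
            log.warning("edge (%s, %s) omitted: %s", var_x, var_y, err)
            continue
        col = np.full(len(df), np.nan)
        have = ~np.isnan(x) & ~np.isnan(y)
        if leave_one_out:
            ref_idx = np.flatnonzero(ref_ok)
            for i in np.flatnonzero(have):
                if i in ref_idx and pts.shape[0] > 3:
                    keep = ref_idx != i
                    loo_line = fit_orthogonal_line(
                        np.column_stack([x[ref_idx[keep]], y[ref_idx[keep]]]),
                        var_x, var_y,
                    )
                    col[i] = orthogonal_distance((x[i], y[i]), loo_line)
                else:
                    col[i] = orthogonal_distance((x[i], y[i]), line)
        else:
            nx_, ny_ = line.normal
            cx, cy = line.centroid
            col[have] = np.abs((x[have] - cx) * nx_ + (y[have] - cy) * ny_)
        values[pd_column_name(var_x, var_y)] = col
        lines[(var_x, var_y)] = line
    return PDMatrix(values, lines, label)


def z_normalize(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Z-transform over non-missing entries (mean 0, sample SD 1); NaN kept.

    Statistics are computed over all available entries, not only the
    reference group, so a one-SD step in the transformed score refers to the
    whole analyzed cohort.
    """
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values to z-normalize")
    mu = arr[ok].mean()
    sd = arr[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot z-normalize")
    out = np.full_like(arr, np.nan)
    out[ok] = (arr[ok] - mu) / sd
    return out


def write_pd_matrix(pdm: PDMatrix, csv_path: str | Path) -> None:
    """CSV of PDs plus a JSON sidecar with per-edge line metadata."""
    csv_path = Path(csv_path)
    out = pdm.values.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(csv_path, index=False, na_rep="")
    meta = {
        "reference_label": pdm.reference_label,
        "lines": {
            pd_column_name(x, y): {
                "var_x": ln.var_x,
                "var_y": ln.var_y,
                "centroid": list(ln.centroid),
                "direction": list(ln.direction),
                "n_fit": ln.n_fit,
                "orthogonal_sse": ln.orthogonal_sse,
            }
            for (x, y), ln in pdm.lines.items()
        },
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_pd_matrix(csv_path: str | Path) -> PDMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col="patient_id")
    df.index = df.index.astype(str)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    lines = {
        (d["var_x"], d["var_y"]): ReferenceLine(
            d["var_x"], d["var_y"], tuple(d["centroid"]), tuple(d["direction"]),
            int(d["n_fit"]), float(d["orthogonal_sse"]),
        )
        for d in meta["lines"].values()
    }
    return PDMatrix(df, lines, meta["reference_label"])
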