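"""Orthogonal regression and parenclitic deviations."""

import numpy as np
import pandas as pd
import pytest

import parenclitic as pc
from parenclitic.deviation import pd_column_name, signed_orthogonal_residual


def brute_force_tls_angle(pts: np.ndarray, n_grid: int = 1_000_000) -> float:
    """Angle-grid minimizer of orthogonal SSE, independent of the eigen route.

    Evaluates the summed squared normal offsets at every grid angle using the
    centered second-moment sums computed directly from the points.
    """
    c = pts.mean(axis=0)
    d = pts - c
    sxx = float((d[:, 0] ** 2).sum())
    syy = float((d[:, 1] ** 2).sum())
    sxy = float((d[:, 0] * d[:, 1]).sum())
    theta = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    # residual along the normal (-sin t, cos t) of a line at angle t
    sse = np.sin(theta) ** 2 * sxx - 2 * np.sin(theta) * np.cos(theta) * sxy + np.cos(theta) ** 2 * syy
    return float(theta[np.argmin(sse)])


def test_exact_line_through_collinear_points():
    line = pc.fit_orthogonal_line([(0, 1), (1, 3), (2, 5)])
    assert line.centroid == pytest.approx((1, 3))
    dx, dy = line.direction
    assert dy / dx == pytest.approx(2.0)
    assert line.orthogonal_sse == pytest.approx(0.0, abs=1e-20)
    assert np.hypot(dx, dy) == pytest.approx(1.0)


def test_fit_matches_angle_grid_oracle(rng):
    for _ in range(20):
        n = rng.integers(5, 60)
        base = rng.normal(size=n)
        pts = np.column_stack(
            [
                base * rng.uniform(0.5, 3) + rng.normal(scale=0.5, size=n),
                base * rng.uniform(-3, 3) + rng.normal(scale=0.5, size=n),
            ]
        )
        line = pc.fit_orthogonal_line(pts)
        theta_fit = np.arctan2(line.direction[1], line.direction[0]) % np.pi
        theta_grid = brute_force_tls_angle(pts, n_grid=100_000)
        diff = min(abs(theta_fit - theta_grid), np.pi - abs(theta_fit - theta_grid))
        assert diff < 2 * np.pi / 100_000


def test_fit_error_conditions():
    with pytest.raises(ValueError, match=">= 3"):
        pc.fit_orthogonal_line([(0, 0), (1, 1)])
    # a perfectly isotropic cloud has no preferred axis
    square = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    with pytest.raises(ValueError, match="ambiguous"):
        pc.fit_orthogonal_line(square)


def test_axis_swap_mirrors_line_and_preserves_distances(rng):
    pts = rng.normal(size=(30, 2)) @ np.array([[2.0, 0.7], [0.7, 1.0]])
    line = pc.fit_orthogonal_line(pts)
    swapped = pc.fit_orthogonal_line(pts[:, ::-1])
    probes = rng.normal(size=(10, 2), scale=3)
    for p in probes:
        d1 = pc.orthogonal_distance(p, line)
        d2 = pc.orthogonal_distance(p[::-1], swapped)
        assert d1 == pytest.approx(d2, abs=1e-9)


def test_distance_textbook_values():
    line = pc.fit_orthogonal_line([(0, 0), (1, 1), (2, 2), (3, 3.0001)])
    assert pc.orthogonal_distance((1, 1), line) == pytest.approx(0.0, abs=1e-4)
    line_yx = pc.fit_orthogonal_line([(-1, -1), (0, 0), (1, 1)])  # exact y = x
    assert pc.orthogonal_distance((0, 1), line_yx) == pytest.approx(np.sqrt(2) / 2)


def test_distance_equals_min_over_sampled_line_points(rng):
    pts = rng.normal(size=(25, 2)) @ np.array([[1.5, 0.4], [0.4, 0.8]])
    line = pc.fit_orthogonal_line(pts)
    c = np.array(line.centroid)
    d = np.array(line.direction)
    ts = np.linspace(-50, 50, 100_001)
    on_line = c + ts[:, None] * d
    for probe in rng.normal(size=(5, 2), scale=2):
        brute = np.min(np.linalg.norm(on_line - probe, axis=1))
        assert pc.orthogonal_distance(probe, line) == pytest.approx(brute, abs=1e-3)


def test_isometry_invariance_and_scaling_non_invariance(rng):
    pts = rng.normal(size=(40, 2)) @ np.array([[2.0, 0.5], [0.5, 1.0]])
    probe = np.array([3.0, -1.0])
    d0 = pc.orthogonal_distance(probe, pc.fit_orthogonal_line(pts))
    # translation
    shift = np.array([10.0, -4.0])
    d_shift = pc.orthogonal_distance(probe + shift, pc.fit_orthogonal_line(pts + shift))
    assert d_shift == pytest.approx(d0, abs=1e-9)
    # rotation
    ang = 0.7
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    d_rot = pc.orthogonal_distance(R @ probe, pc.fit_orthogonal_line(pts @ R.T))
    assert d_rot == pytest.approx(d0, abs=1e-9)
    # per-axis rescaling changes the geometry: documented non-invariance
    S = np.diag([3.0, 1.0])
    d_scaled = pc.orthogonal_distance(S @ probe, pc.fit_orthogonal_line(pts @ S))
    assert abs(d_scaled - d0) > 1e-3


def test_signed_residuals_sum_to_zero(rng):
    pts = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.6], [0.6, 2.0]])
    line = pc.fit_orthogonal_line(pts)
    s = sum(signed_orthogonal_residual(p, line) for p in pts)
    scale = np.abs(pts).max()
    assert abs(s) / scale < 1e-9


def test_reference_mean_pd_matches_half_normal(rng):
    """Isotropic noise sigma around a line: mean reference PD ~ 0.8 sigma."""
    sigma = 0.7
    n = 10_000
    t = rng.uniform(-5, 5, n)
    pts = np.column_stack([t, 2 * t + 1]) + rng.normal(scale=sigma, size=(n, 2))
    line = pc.fit_orthogonal_line(pts)
    nx, ny = line.normal
    cx, cy = line.centroid
    pd_vals = np.abs((pts[:, 0] - cx) * nx + (pts[:, 1] - cy) * ny)
    assert 0.6 * sigma < pd_vals.mean() < 0.9 * sigma


def test_compute_pd_matrix_geometry_and_missingness(small_cohort):
    cohort, _ = small_cohort
    df = cohort.df.copy()
    # plant reference exactly on y = 2x + 1 for a pair, probe offset along y
    x = np.linspace(1, 5, len(df))
    df["urea"] = x
    df["creatinine"] = 2 * x + 1
    df.loc[df.index[0], "creatinine"] = 2 * x[0] + 1 + np.sqrt(5)
    df.loc[df.index[1], "urea"] = np.nan
    planted = pc.CohortTable(cohort.registry, df)
    pdm = pc.compute_pd_matrix(planted, lambda d: d.index >= 2, [("urea", "creatinine")])
    col = pdm.column("urea", "creatinine")
    # probe: vertical offset sqrt(5) against slope-2 line -> distance 1.0
    assert col.iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert np.isnan(col.iloc[1])
    assert col.iloc[2:].abs().max() < 1e-9
    assert (col.dropna() >= 0).all()


def test_pd_available_n_matches_pairwise_complete_cases(small_cohort):
    cohort, _ = small_cohort
    edge = ("arterial_ph", "bicarbonate")
    pdm = pc.compute_pd_matrix(cohort, "survived30", [edge])
    _, _, n_pairs = pc.pairwise_pearson(
        cohort.labs["arterial_ph"], cohort.labs["bicarbonate"]
    )
    assert int(pdm.column(*edge).notna().sum()) == n_pairs


def test_pd_invariant_under_axis_swap(small_cohort):
    cohort, _ = small_cohort
    a = pc.compute_pd_matrix(cohort, "survived30", [("arterial_ph", "bicarbonate")])
    b = pc.compute_pd_matrix(cohort, "survived30", [("bicarbonate", "arterial_ph")])
    va = a.column("arterial_ph", "bicarbonate").to_numpy()
    vb = b.column("bicarbonate", "arterial_ph").to_numpy()
    np.testing.assert_allclose(va, vb, atol=1e-9, equal_nan=True)


def test_edge_with_insufficient_reference_pairs_is_omitted(small_cohort):
    cohort, _ = small_cohort
    df = cohort.df.copy()
    df["alt"] = np.nan
    pdm = pc.compute_pd_matrix(
        pc.CohortTable(cohort.registry, df), "survived30",
        [("inr", "alt"), ("arterial_ph", "bicarbonate")],
    )
    assert pdm.edges == [("arterial_ph", "bicarbonate")]


def test_z_normalize_contract():
    np.testing.assert_allclose(pc.z_normalize([1, 2, 3]), [-1, 0, 1])
    out = pc.z_normalize([5.0, np.nan, 7.0, 3.0])
    assert np.isnan(out[1])
    ok = out[~np.isnan(out)]
    assert ok.mean() == pytest.approx(0, abs=1e-12)
    assert ok.std(ddof=1) == pytest.approx(1, abs=1e-12)
    with pytest.raises(ValueError, match="zero spread"):
        pc.z_normalize([5, 5, np.nan, 5])


def test_pd_matrix_round_trip(tmp_path, small_cohort):
    cohort, _ = small_cohort
    pdm = pc.compute_pd_matrix(
        cohort, "survived30",
        [("arterial_ph", "bicarbonate"), ("urea", "creatinine")],
    )
    path = tmp_path / "pd.csv"
    pc.write_pd_matrix(pdm, path)
    back = pc.read_pd_matrix(path)
    assert back.reference_label == pdm.reference_label
    assert back.edges == pdm.edges
    np.testing.assert_allclose(
        back.values.to_numpy(), pdm.values.to_numpy(), rtol=1e-12, equal_nan=True
    )
    for edge in pdm.edges:
        assert back.lines[edge].centroid == pytest.approx(pdm.lines[edge].centroid)
        assert back.lines[edge].direction == pytest.approx(pdm.lines[edge].direction)
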