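"""Mann-Whitney, Cox, ROC/DeLong, Kaplan-Meier and the pipeline chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import parenclitic as pc


# Published-table regression fixtures: (U, n0, n1, r to 3 dp) for the
# mortality and deterioration group comparisons of the parenclitic scores.
MORTALITY_ROWS = [
    (2164, 127, 31, 0.068),
    (613, 54, 19, 0.147),
    (1342, 64, 29, 0.356),
    (2409, 127, 32, 0.128),
    (2328, 119, 31, 0.183),
    (844.5, 53, 20, 0.455),
    (927.5, 60, 19, 0.461),
    (2409, 127, 32, 0.128),
]
DETERIORATION_ROWS = [
    (2001, 129, 29, 0.047),
    (523, 56, 17, 0.072),
    (1242, 68, 25, 0.352),
    (2585.5, 131, 29, 0.240),
    (2341.5, 131, 28, 0.182),
    (678, 54, 19, 0.243),
    (817, 61, 18, 0.352),
    (982.5, 64, 25, 0.177),
    (1239, 105, 26, 0.064),
]


@pytest.mark.parametrize("U,n0,n1,expected", MORTALITY_ROWS + DETERIORATION_ROWS)
def test_effect_size_reproduces_published_cells(U, n0, n1, expected):
    assert pc.effect_size_from_u(U, n0, n1) == pytest.approx(expected, abs=5e-4)


def test_mann_whitney_identical_samples():
    a = np.arange(10.0)
    gc = pc.mann_whitney(a, a)
    assert gc.U == pytest.approx(100 / 2)
    assert abs(gc.Z) < 1e-12
    assert gc.effect_r == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a=st.lists(st.integers(0, 12), min_size=1, max_size=8),
    b=st.lists(st.integers(0, 12), min_size=1, max_size=8),
)
def test_mann_whitney_u_matches_exhaustive_pair_count(a, b):
    gc = pc.mann_whitney(a, b)
    brute = sum(
        1.0 if bj > ai else (0.5 if bj == ai else 0.0) for ai in a for bj in b
    )
    assert gc.U == pytest.approx(brute)


def test_mann_whitney_orientation_and_effect(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(1.5, 1, 25)  # comparison group runs higher
    gc = pc.mann_whitney(a, b)
    assert gc.U / (gc.n0 * gc.n1) > 0.5
    assert gc.p < 0.001
    with pytest.raises(ValueError):
        pc.mann_whitney([], [1.0])


def test_cox_null_covariate(rng):
    n = 1000
    x = rng.normal(size=n)
    t = rng.exponential(10, n)
    time = np.minimum(t, 30)
    event = (t < 30).astype(float)
    res = pc.cox_fit(time, event, pd.DataFrame({"x": x}))
    row = res.row("x")
    assert abs(row.beta) < 0.15
    assert row.ci95[0] < 1 < row.ci95[1]


def test_cox_recovers_log2_hazard(rng):
    """Exponential survival, beta = log 2 on a standard-normal covariate."""
    n = 2000
    x = rng.normal(size=n)
    rate = 0.05 * np.exp(np.log(2) * x)
    t = rng.exponential(1 / rate)
    time = np.minimum(t, 30)
    event = (t < 30).astype(float)
    res = pc.cox_fit(time, event, pd.DataFrame({"x": x}))
    assert 1.75 < res.row("x").hazard_ratio < 2.30


def test_cox_two_group_rate_ratio(rng):
    n = 3000
    g = (rng.random(n) < 0.5).astype(float)
    rate = 0.03 * 3.0**g
    t = rng.exponential(1 / rate)
    time = np.minimum(t, 30)
    event = (t < 30).astype(float)
    res = pc.cox_fit(time, event, pd.DataFrame({"g": g}))
    assert 2.6 < res.row("g").hazard_ratio < 3.4


def test_cox_requires_events():
    with pytest.raises(ValueError, match="no events"):
        pc.cox_fit([1, 2, 3], [0, 0, 0], pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


def test_cox_invariants_and_complete_case(rng):
    n = 300
    x = rng.normal(size=n)
    x[:20] = np.nan
    t = rng.exponential(15, n)
    res = pc.cox_fit(np.minimum(t, 30), (t < 30).astype(float), pd.DataFrame({"x": x}))
    assert res.dropped_n == 20
    assert res.model_n == 280
    row = res.row("x")
    assert row.hazard_ratio > 0
    assert row.ci95[0] < row.hazard_ratio < row.ci95[1]


def test_roc_perfect_separation():
    roc = pc.roc_analysis([0.1, 0.2, 0.3, 2.1, 2.2], [0, 0, 0, 1, 1])
    assert roc.auc == 1.0
    assert roc.sensitivity == 1.0 and roc.specificity == 1.0
    assert roc.youden_j == pytest.approx(1.0)


def test_roc_null_scores(rng):
    s = rng.normal(size=2000)
    y = (rng.random(2000) < 0.3).astype(int)
    roc = pc.roc_analysis(s, y)
    assert roc.auc == pytest.approx(0.5, abs=0.03)


def test_auc_equals_u_identity(rng):
    """Shared-rank identity AUC = U / (n0 * n1), exact on any data."""
    for _ in range(5):
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.25).astype(int)
        s[y == 1] += rng.uniform(0, 2)
        roc = pc.roc_analysis(s, y)
        gc = pc.mann_whitney(s[y == 0], s[y == 1])
        assert roc.auc == pytest.approx(gc.U / (gc.n0 * gc.n1), abs=1e-12)


def test_auc_orientation_flip(rng):
    s = rng.normal(size=300)
    y = (s < -0.5).astype(int)  # lower score = positive class
    roc = pc.roc_analysis(s, y)
    assert roc.flipped
    assert roc.auc > 0.5


def test_delong_identical_scores(rng):
    s = rng.normal(size=100)
    y = (rng.random(100) < 0.4).astype(int)
    delta, z, p = pc.delong_compare(s, s, y)
    assert delta == 0.0 and p == 1.0


def test_delong_variance_close_to_bootstrap(rng):
    n = 500
    s = rng.normal(size=n)
    y = (rng.random(n) < 0.3).astype(int)
    s[y == 1] += 0.8
    from parenclitic.survival import _auc_variance

    auc, var = _auc_variance(s[y == 1], s[y == 0])
    boot = []
    for _ in range(400):
        idx = rng.integers(0, n, n)
        sb, yb = s[idx], y[idx]
        if yb.sum() in (0, n):
            continue
        a, _ = _auc_variance(sb[yb == 1], sb[yb == 0])
        boot.append(a)
    assert var == pytest.approx(np.var(boot, ddof=1), rel=0.15)


def test_delong_detects_better_classifier(rng):
    n = 600
    y = (rng.random(n) < 0.35).astype(int)
    good = rng.normal(size=n) + 1.5 * y
    bad = rng.normal(size=n)
    delta, z, p = pc.delong_compare(good, bad, y)
    assert delta > 0.15 and p < 0.001


def test_delong_paired_requires_overlap():
    s = np.full(20, np.nan)
    s[:5] = 1.0
    with pytest.raises(ValueError, match=">= 10"):
        pc.delong_compare(s, np.ones(20), np.tile([0, 1], 10), mode="paired")


def test_km_hand_computed_product_limit():
    km = pc.km_estimate([1, 2, 3], [1, 1, 0])
    # S = 2/3 after t=1, 1/3 after t=2, censoring at 3 leaves it there
    surv = dict(zip(km.times, km.survival))
    assert surv[1.0] == pytest.approx(2 / 3)
    assert surv[2.0] == pytest.approx(1 / 3)
    assert km.survival[-1] == pytest.approx(1 / 3)


def test_km_no_events_flat_curve():
    km = pc.km_estimate([5, 10, 30], [0, 0, 0])
    assert np.allclose(km.survival, 1.0)
    assert km.survival_at_horizon == 1.0


def test_km_matches_independent_product(rng):
    t = np.round(rng.exponential(10, 200), 0) + 1
    e = (rng.random(200) < 0.7).astype(float)
    km = pc.km_estimate(t, e)
    # independent product-limit computation
    s = 1.0
    for ti in np.sort(np.unique(t[e == 1])):
        n_at_risk = (t >= ti).sum()
        d = ((t == ti) & (e == 1)).sum()
        s *= 1 - d / n_at_risk
    assert km.survival[-1] == pytest.approx(s, abs=1e-12)


def test_logrank_identical_groups(rng):
    t = rng.exponential(10, 100)
    e = (t < 30).astype(float)
    time = np.minimum(t, 30)
    g = np.tile([0, 1], 50)
    # same survival law in both arms
    res = pc.logrank(time, e, g)
    assert res.p > 0.01
    with pytest.raises(ValueError, match="2 groups"):
        pc.logrank(time, e, np.zeros(100))


def test_pipeline_finds_planted_edge_and_only_it(large_cohort):
    """End to end: the planted acid-base axis survives every stage."""
    cohort, truth = large_cohort
    net = pc.build_network(cohort, "survived30")
    edges = [(e.var_x, e.var_y) for e in net.significant_edges()]
    pdm = pc.compute_pd_matrix(cohort, "survived30", edges)
    bundle = pc.run_survival_pipeline(cohort, pdm)
    planted = "PD__arterial_ph__bicarbonate"
    assert planted in bundle["edges"]
    entry = bundle["edges"][planted]
    assert entry["group_comparison"]["p"] < 0.05
    hr_row = [r for r in entry["cox"]["rows"] if r["covariate"] == planted][0]
    assert hr_row["p"] < 0.05
    assert hr_row["hazard_ratio"] > 1.3
    assert "roc" in entry and entry["roc"]["auc"] > 0.6
    assert "km" in entry
    km = entry["km"]
    assert km["survival_at_30_beyond_cutoff"] < km["survival_at_30_below_cutoff"]
    assert km["logrank_p"] < 0.05


def test_pipeline_null_cohort_reaches_no_cox_significance(small_cohort):
    """PDs of pure-noise labs should not clear the Cox stage."""
    cohort, _ = small_cohort
    rs = np.random.default_rng(11)
    df = cohort.df.copy()
    for name in cohort.lab_names:
        df[name] = rs.normal(size=len(df))
    noise = pc.CohortTable(cohort.registry, df)
    pdm = pc.compute_pd_matrix(
        noise, "survived30", [("arterial_ph", "bicarbonate"), ("urea", "creatinine")]
    )
    bundle = pc.run_survival_pipeline(noise, pdm)
    assert all("roc" not in e for e in bundle["edges"].values())


def test_pipeline_report_deterministic(tmp_path, small_cohort):
    cohort, _ = small_cohort
    pdm = pc.compute_pd_matrix(cohort, "survived30", [("arterial_ph", "bicarbonate")])
    bundle = pc.run_survival_pipeline(cohort, pdm)
    pc.write_report(bundle, tmp_path / "a")
    pc.write_report(bundle, tmp_path / "b")
    for name in [
        "table2_group_comparison.csv", "table4_cox.csv", "table6_roc.csv",
        "km_curves.csv", "report.json",
    ]:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
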