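"""Survival statistics against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mipssr.simulate import SimConfig, simulate_cohort
from mipssr.survival import (
    CoxFitError,
    cox_fit,
    km_estimate,
    lasso_cox,
    logrank_test,
    td_roc,
    uni_cox_screen,
    validate_groups,
)

# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_all_events_product_limit_by_hand():
    curve = km_estimate([1, 2, 3], [1, 1, 1])
    assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0], abs=1e-12)
    assert curve.median == 2


def test_km_single_censored_observation():
    curve = km_estimate([5], [0])
    assert (curve.survival == 1.0).all()
    assert curve.median is None
    assert curve.median_label == ">5"


def test_km_with_censoring_by_hand():
    # times 1+, 2, 2, 3+ : at t=2 risk set is 3, two deaths -> S = 1/3
    curve = km_estimate([1, 2, 2, 3], [0, 1, 1, 0])
    s_at_2 = curve.survival[np.where(curve.times == 2)[0][0]]
    assert s_at_2 == pytest.approx(1 / 3, abs=1e-12)
    assert curve.median == 2


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(5)
    t = rng.exponential(10, size=60).round(2)  # a few ties
    curve = km_estimate(t, np.ones_like(t))
    for ti, si in zip(curve.times, curve.survival):
        assert si == pytest.approx((t > ti).mean(), abs=1e-12)


def test_km_rejects_nonpositive_times():
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# Log-rank


def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 1]
    res = logrank_test([(t, e), (t, e)])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)
    assert res.df == 1


def _logrank_2sample_by_hand(t1, e1, t2, e2):
    """Textbook O-E/V computation over pooled event times."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_hand_oracle():
    t1 = np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
    e1 = np.array([1, 1, 0, 1, 1, 0])
    t2 = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    e2 = np.array([1, 1, 1, 0, 1])
    expected = _logrank_2sample_by_hand(t1, e1, t2, e2)
    res = logrank_test([(t1, e1), (t2, e2)])
    assert res.chi2 == pytest.approx(expected, abs=1e-10)


def test_logrank_needs_two_groups():
    with pytest.raises(ValueError):
        logrank_test([([1.0], [1])])


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _neg_pl_1d(beta, x, t, e):
    """Hand-written 1-D log partial likelihood (no ties in the data)."""
    eta = beta * x
    ll = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return -ll


def test_cox_single_covariate_matches_grid_maximization():
    x = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
    t = np.array([3.0, 1.0, 6.0, 2.0, 4.0, 8.0, 5.0, 7.0])
    e = np.array([1, 1, 1, 1, 1, 0, 1, 1])
    best = minimize_scalar(
        _neg_pl_1d, args=(x, t, e), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    fit = cox_fit(df, "time", "event", ["x"])
    assert fit.coef["x"] == pytest.approx(best.x, abs=1e-6)
    assert fit.hr["x"] == pytest.approx(np.exp(best.x), abs=1e-5)
    assert 0 < fit.p["x"] <= 1


def test_cox_breslow_agrees_without_ties():
    rng = np.random.default_rng(9)
    x = rng.normal(size=120)
    t = rng.exponential(np.exp(-0.5 * x))
    df = pd.DataFrame({"time": t, "event": 1, "x": x})
    fe = cox_fit(df, "time", "event", ["x"])
    fb = cox_fit(df, "time", "event", ["x"], ties="breslow")
    assert fb.coef["x"] == pytest.approx(fe.coef["x"], abs=1e-4)
    assert fb.se["x"] == pytest.approx(fe.se["x"], rel=1e-3)


def test_cox_parameter_recovery():
    rng = np.random.default_rng(11)
    n = 1000
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.7 * x))
    df = pd.DataFrame({"time": t, "event": 1, "x": x})
    fit = cox_fit(df, "time", "event", ["x"])
    assert fit.coef["x"] == pytest.approx(0.7, abs=0.1)


def test_cox_degenerate_designs_raise():
    df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [2.0, 2.0, 2.0]})
    with pytest.raises(CoxFitError, match="constant"):
        cox_fit(df, "time", "event", ["x"])
    df2 = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [1.0, 2.0]})
    with pytest.raises(CoxFitError, match="zero events"):
        cox_fit(df2, "time", "event", ["x"])


# ---------------------------------------------------------------------------
# LASSO-Cox


@pytest.fixture(scope="module")
def lasso_cohort():
    cohort = simulate_cohort(SimConfig(n=600, seed=21))
    rng = np.random.default_rng(22)
    for i in range(6):
        cohort[f"noise{i}"] = rng.normal(size=len(cohort))
    return cohort


def test_lasso_full_shrinkage_at_huge_lambda(lasso_cohort):
    path = lasso_cox(
        lasso_cohort, "os_months", "event",
        ["mut_points", "ipssr_total", "noise0", "noise1"],
        lambdas=[1e6, 1e-3], k_folds=5, seed=3,
    )
    assert (path.coef_path[1e6].abs() < 1e-12).all()


def test_lasso_unpenalized_limit_matches_cox(lasso_cohort):
    covs = ["mut_points", "ipssr_total"]
    path = lasso_cox(lasso_cohort, "os_months", "event", covs, lambdas=[0.0], k_folds=5, seed=3)
    fit = cox_fit(lasso_cohort, "os_months", "event", covs)
    assert np.max(np.abs(path.coef_min.to_numpy() - fit.coef.to_numpy())) < 1e-4


def test_lasso_selects_true_predictors(lasso_cohort):
    covs = ["mut_points", "ipssr_total"] + [f"noise{i}" for i in range(6)]
    hits = 0
    for seed in range(5):
        path = lasso_cox(lasso_cohort, "os_months", "event", covs, k_folds=5, seed=seed)
        if {"mut_points", "ipssr_total"} <= set(path.selected):
            hits += 1
    assert hits >= 4  # the true pair survives CV selection almost always


def test_lasso_requires_seed_and_enough_folds(lasso_cohort):
    with pytest.raises(TypeError):
        lasso_cox(lasso_cohort, "os_months", "event", ["mut_points"])  # no seed
    with pytest.raises(ValueError):
        lasso_cox(lasso_cohort, "os_months", "event", ["mut_points"], k_folds=2, seed=1)


# ---------------------------------------------------------------------------
# Time-dependent ROC


def test_td_roc_perfect_marker_no_censoring():
    t = np.arange(1.0, 21.0)
    marker = -t  # larger marker = earlier death
    res = td_roc(marker, t, np.ones_like(t), horizon=10.0)
    assert res.auc == pytest.approx(1.0, abs=1e-12)


def _roc_by_enumeration(marker, time, event, horizon):
    """Brute-force ROC for uncensored data: empirical case/control split."""
    case = time <= horizon
    pts = [(0.0, 0.0)]
    for c in np.unique(marker):
        tpr = (marker[case] > c).mean()
        fpr = (marker[~case] > c).mean()
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    pts = sorted(pts)
    return np.trapezoid([p[1] for p in pts], [p[0] for p in pts])


def test_td_roc_matches_enumeration_on_toy_data():
    marker = np.array([0.3, 2.0, 1.1, 0.7])
    time = np.array([2.0, 1.0, 3.0, 9.0])
    event = np.array([1, 1, 1, 1])
    res = td_roc(marker, time, event, horizon=4.0)
    assert res.auc == pytest.approx(
        _roc_by_enumeration(marker, time, event, 4.0), abs=1e-12
    )


def test_td_roc_invariant_under_monotone_marker_transform():
    rng = np.random.default_rng(17)
    n = 300
    marker = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.8 * marker))
    e = (rng.random(n) > 0.2).astype(int)
    horizon = float(np.median(t))
    a1 = td_roc(marker, t, e, horizon).auc
    a2 = td_roc(np.exp(3 * marker) + 7, t, e, horizon).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_td_roc_input_errors():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 1, 1])
    m = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        td_roc(m, t, e, horizon=99.0)  # beyond follow-up
    with pytest.raises(ValueError):
        td_roc(m, t, e, horizon=0.5)  # no cases yet


# ---------------------------------------------------------------------------
# Screens and validation report


def test_uni_cox_screen_flags_constant_and_ranks_driver():
    cohort = simulate_cohort(SimConfig(n=400, seed=31))
    cohort["constant"] = 1.0
    rng = np.random.default_rng(32)
    cohort["noise"] = rng.normal(size=len(cohort))
    table = uni_cox_screen(
        cohort, "os_months", "event",
        ["true_linear_predictor", "noise", "constant"],
    )
    assert table.loc[table.factor == "constant", "status"].iloc[0].startswith("failed")
    ok = table[table.status == "ok"]
    assert ok.iloc[0]["factor"] == "true_linear_predictor"  # smallest p first
    assert ((ok["p"] > 0) & (ok["p"] <= 1)).all()
    assert (ok["hr"] > 0).all()


def test_validate_groups_report():
    cohort = simulate_cohort(SimConfig(n=400, seed=33))
    scored_group = np.where(cohort["mut_points"] >= 2, "high_mut", "low_mut")
    cohort["grp"] = scored_group
    report = validate_groups(
        cohort, "os_months", "event", "grp",
        horizon=24.0, markers={"truth": "true_linear_predictor"},
    )
    assert set(report["median_os_by_group"]) == {"high_mut", "low_mut"}
    assert report["logrank"]["p"] < 0.05
    assert 0.5 < report["auc"]["truth"] <= 1.0
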