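"""Nested logistic/linear models, AUC, LR tests, stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from realgait.association_analysis import (
    FitResult,
    ModelSpec,
    NestedComparison,
    SeparationError,
    compare_nested,
    compute_auc,
    fit_linear,
    fit_logistic,
    run_frailty_analysis,
    run_grip_analysis,
    sensitivity_age65,
    sensitivity_exclude_runners,
    stepwise_forward,
)
from realgait.synthetic_data import simulate_association_cohort


def test_auc_worked_example():
    """Enumerating all four positive-negative pairs gives 0.75."""
    assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_extremes_and_ties():
    assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert compute_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5
    assert compute_auc([0.3, 0.3, 0.7], [0, 1, 1]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        compute_auc([0.1, 0.2], [1, 1])


def test_auc_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 500)
    s = rng.normal(size=500) + y  # informative scores with ties unlikely
    assert compute_auc(s, y) == pytest.approx(sk.roc_auc_score(y, s), abs=1e-12)


def _fit(k, ll, n=100, outcome="frail", metrics=()):
    return FitResult(
        spec=ModelSpec(outcome, tuple(metrics)),
        params=pd.Series(dtype=float),
        log_likelihood=ll,
        n=n,
        k=k,
        aic=2 * k - 2 * ll,
        bic=k * np.log(n) - 2 * ll,
    )


def test_information_criteria_identity():
    f = _fit(k=2, ll=-10.0)
    assert f.aic == pytest.approx(24.0, abs=1e-12)
    assert f.bic == pytest.approx(2 * np.log(100) + 20, abs=1e-12)


def test_compare_nested():
    a = _fit(k=5, ll=-50.0)
    b = _fit(k=6, ll=-50.0, metrics=("m",))
    c = compare_nested(a, b)
    assert c.lr_stat == 0.0 and c.p_value == pytest.approx(1.0)
    b2 = _fit(k=6, ll=-50.0 + 3.841 / 2, metrics=("m",))
    assert compare_nested(a, b2).p_value == pytest.approx(0.050, abs=0.001)
    with pytest.raises(RuntimeError):
        compare_nested(a, _fit(k=6, ll=-60.0, metrics=("m",)))
    with pytest.raises(ValueError):
        compare_nested(b, a)  # not nested


def test_logistic_null_covariate():
    """Noise covariate: coefficient near zero, AUC gain negligible."""
    table, _ = simulate_association_cohort(5000, seed=42, effect=0.0)
    fit = fit_logistic(table, ModelSpec("frail", ("p95_medium",)))
    assert abs(fit.params["p95_medium"]) < 3 * fit.bse["p95_medium"] + 1e-9
    base = fit_logistic(table, ModelSpec("frail"))
    assert fit.auc == pytest.approx(base.auc, abs=0.02)
    # identities hold on real fits
    assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood, abs=1e-9)
    assert fit.bic == pytest.approx(
        fit.k * np.log(fit.n) - 2 * fit.log_likelihood, abs=1e-9
    )


def test_logistic_separation_error():
    table, _ = simulate_association_cohort(500, seed=1, effect=0.0)
    table["perfect"] = table["frail"].astype(float)
    with pytest.raises(SeparationError):
        fit_logistic(table, ModelSpec("frail", ("perfect",)))


def test_linear_exact_fit():
    table, _ = simulate_association_cohort(400, seed=3, effect=0.0)
    table["grip_kg"] = (
        30.0
        + 5.0 * (table["sex"] == "man")
        - 2.0 * (table["age_group"] == "75+")
        + 1.5 * table["p95_medium"]
    )
    fit = fit_linear(table, ModelSpec("grip_kg", ("p95_medium",)))
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)
    assert fit.params["p95_medium"] == pytest.approx(1.5, abs=1e-8)


def test_linear_hand_computed_regression():
    """4-point simple regression against the closed-form normal equations."""
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 2.0, 4.0])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    import statsmodels.api as sm

    res = sm.OLS(y, sm.add_constant(x)).fit()
    assert res.params[1] == pytest.approx(slope)
    assert res.params[0] == pytest.approx(intercept)


def test_stepwise_selects_true_predictor():
    table, _ = simulate_association_cohort(2000, seed=11, effect=0.6)
    rng = np.random.default_rng(99)
    noise_cols = []
    for i in range(7):
        col = f"noise_{i}"
        table[col] = rng.normal(size=len(table))
        noise_cols.append(col)
    res = stepwise_forward(
        table, ModelSpec("frail"), ["p95_medium"] + noise_cols
    )
    assert res.selected[0] == "p95_medium"
    assert all(p < 0.05 for p in res.entry_p_values)


def test_stepwise_empty_candidates():
    table, _ = simulate_association_cohort(500, seed=2, effect=0.0)
    res = stepwise_forward(table, ModelSpec("frail"), [])
    assert res.selected == []
    assert res.final_fit.spec.metrics == ()


def _metric_table(n=400, seed=5, effect=0.6):
    table, _ = simulate_association_cohort(n, seed=seed, effect=effect)
    rng = np.random.default_rng(seed + 1)
    for cat in ("short", "medium", "long"):
        for m in ("mode", "median", "mean", "p75", "p90", "p95", "max", "sd"):
            col = f"{m}_{cat}"
            if col not in table:
                table[col] = table["p95_medium"] + rng.normal(0, 0.05, n)
    table["p95_all"] = table["p95_medium"] + 0.05
    return table


def test_run_frailty_analysis_shape_and_aic_gain():
    table = _metric_table(n=2000, seed=6)
    report = run_frailty_analysis(table)
    assert len(report) == 24  # 3 categories x 8 metrics
    p95 = report[(report.metric == "p95") & (report.duration == "medium")].iloc[0]
    assert p95["aic_b"] < p95["aic_a"]  # true effect improves fit
    assert p95["auc_b"] > p95["auc_a"]


def test_run_analysis_single_category():
    table = _metric_table(n=600, seed=7)
    only_short = table.drop(
        columns=[c for c in table.columns if c.endswith(("_medium", "_long"))]
    )
    report = run_frailty_analysis(only_short)
    assert set(report["duration"]) == {"short"}


def test_grip_analysis_runs():
    table = _metric_table(n=600, seed=8)
    report = run_grip_analysis(table)
    assert {"adj_r2_a", "adj_r2_b", "lr", "p_value"} <= set(report.columns)


def test_sensitivity_filters():
    table = _metric_table(n=300, seed=9)
    same, n_excl = sensitivity_exclude_runners(table, max_walk_speed=np.inf)
    assert n_excl == 0 and len(same) == len(table)
    thresh = float(table["p95_all"].median())
    filtered, n_excl = sensitivity_exclude_runners(table, max_walk_speed=thresh)
    assert n_excl == int((table["p95_all"] > thresh).sum())  # direct-count oracle
    sub = sensitivity_age65(table)
    assert (sub["age"] >= 65).all()
    assert len(sub) == int((table["age"] >= 65).sum())
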