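"""Nested regression models linking speed metrics to frailty and grip.

Model A regresses the outcome (frailty: logistic; handgrip strength:
linear) on the base covariates — sex, age group, BMI category and
physical-activity level, dummy-coded with the first level as reference.
Model B adds one or more speed-metric columns. Models are compared by the
likelihood-ratio test, AUC (logistic) or adjusted R² (linear), and
AIC/BIC. A forward stepwise procedure with an entry p-value selects speed
metrics. Two sensitivity analyses filter the cohort: exclusion of
probable runners (high 95th-percentile speed over all bouts) and
restriction to ages 65+.

Significance is flagged at both 0.05 and the stricter 0.001 headline
level used when many metric × duration combinations are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BASE_COVARIATES",
    "ModelSpec",
    "FitResult",
    "NestedComparison",
    "StepwiseResult",
    "build_design",
    "fit_logistic",
    "fit_linear",
    "compare_nested",
    "compute_auc",
    "stepwise_forward",
    "run_frailty_analysis",
    "run_grip_analysis",
    "sensitivity_exclude_runners",
    "sensitivity_age65",
]

BASE_COVARIATES = ["sex", "age_group", "bmi_category", "pa_level"]
ALPHA_HEADLINE = 0.001
ALPHA_NOMINAL = 0.05


class SeparationError(RuntimeError):
    """Raised when a logistic fit fails to converge (e.g. perfect separation)."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str                      # "frail" or "grip_kg"
    metrics: Tuple[str, ...] = ()     # speed-metric columns added to the base

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return self.outcome == other.outcome and set(self.metrics) <= set(other.metrics)


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    log_likelihood: float
    n: int
    k: int
    aic: float
    bic: float
    auc: Optional[float] = None
    adj_r2: Optional[float] = None
    bse: Optional[pd.Series] = None


@dataclass
class NestedComparison:
    lr_stat: float
    df: int
    p_value: float


@dataclass
class StepwiseResult:
    selected: List[str]
    entry_p_values: List[float]
    final_fit: FitResult


def build_design(table: pd.DataFrame, metrics: Sequence[str] = ()) -> pd.DataFrame:
    """Design matrix: intercept + dummy-coded base covariates + metrics.

    Dummy coding drops the first category of each base covariate
    (reference level). Metric columns are used as-is (continuous).
    """
    missing = [c for c in list(BASE_COVARIATES) + list(metrics) if c not in table]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    X = pd.get_dummies(
        table[BASE_COVARIATES], drop_first=True, dtype=float
    )
    # levels absent from this subset (e.g. young groups in the 65+ analysis)
    # would yield all-zero columns and a singular design
    X = X.loc[:, (X != 0).any(axis=0)]
    for m in metrics:
        X[m] = table[m].astype(float)
    X.insert(0, "const", 1.0)
    return X


def _complete_rows(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.outcome] + BASE_COVARIATES + list(spec.metrics)
    return table.dropna(subset=[c for c in cols if c in table])


def fit_logistic(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood logistic fit with in-sample AUC.

    Newton iterations to tolerance 1e-8; non-convergence or quasi-perfect
    separation raises :class:`SeparationError` with diagnostics.
    """
    data = _complete_rows(table, spec)
    y = data[spec.outcome].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must be binary with both classes present")
    X = build_design(data, spec.metrics)
    try:
        res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except Exception as exc:  # PerfectSeparation, singular Hessian, ...
        raise SeparationError(f"logistic fit failed for {spec}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(f"logistic fit did not converge for {spec}")
    if np.abs(res.params).max() > 50:
        raise SeparationError(
            f"diverging coefficients suggest separation for {spec}: "
            f"{res.params.abs().idxmax()}"
        )
    k = X.shape[1]
    ll = float(res.llf)
    auc = compute_auc(res.predict(X), y)
    return FitResult(
        spec=spec,
        params=res.params,
        log_likelihood=ll,
        n=len(y),
        k=k,
        aic=2 * k - 2 * ll,
        bic=k * np.log(len(y)) - 2 * ll,
        auc=auc,
        bse=res.bse,
    )


def fit_linear(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS fit with Gaussian log-likelihood for AIC/BIC and adjusted R².

    ``k`` counts the mean parameters (regressors including the intercept).
    """
    data = _complete_rows(table, spec)
    y = data[spec.outcome].astype(float).to_numpy()
    X = build_design(data, spec.metrics)
    res = sm.OLS(y, X).fit()
    k = X.shape[1]
    ll = float(res.llf)
    return FitResult(
        spec=spec,
        params=res.params,
        log_likelihood=ll,
        n=len(y),
        k=k,
        aic=2 * k - 2 * ll,
        bic=k * np.log(len(y)) - 2 * ll,
        adj_r2=float(res.rsquared_adj),
        bse=res.bse,
    )


def compare_nested(fit_a: FitResult, fit_b: FitResult) -> NestedComparison:
    """Likelihood-ratio test of nested fits on the same rows."""
    if not fit_a.spec.is_nested_in(fit_b.spec):
        raise ValueError("model A must be nested in model B")
    if fit_a.n != fit_b.n:
        raise ValueError("nested fits must use the same rows")
    lr = 2.0 * (fit_b.log_likelihood - fit_a.log_likelihood)
    if lr < -1e-6:
        raise RuntimeError(
            "log-likelihood decreased under nesting: convergence failure"
        )
    lr = max(lr, 0.0)
    df = fit_b.k - fit_a.k
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return NestedComparison(lr_stat=float(lr), df=df, p_value=p)


def compute_auc(scores, labels) -> float:
    """AUC as the Mann–Whitney probability with ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # average ranks handle ties
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stepwise_forward(
    table: pd.DataFrame,
    base: ModelSpec,
    candidates: Sequence[str],
    p_entry: float = 0.05,
    kind: str = "logistic",
) -> StepwiseResult:
    """Forward stepwise selection by likelihood-ratio entry test.

    At each step the candidate with the smallest LR p-value against the
    current model enters while p < ``p_entry``; ties break by candidate
    order. Deterministic given the table.
    """
    fit_fn = fit_logistic if kind == "logistic" else fit_linear
    rows = table.dropna(subset=list(candidates)) if candidates else table
    current = fit_fn(rows, base)
    selected: List[str] = []
    entry_ps: List[float] = []
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            spec = ModelSpec(base.outcome, tuple(list(current.spec.metrics) + [cand]))
            try:
                fit = fit_fn(rows, spec)
                p = compare_nested(current, fit).p_value
            except (SeparationError, RuntimeError):
                continue
            if best is None or p < best[0]:
                best = (p, cand, fit)
        if best is None or best[0] >= p_entry:
            break
        p, cand, fit = best
        selected.append(cand)
        entry_ps.append(p)
        remaining.remove(cand)
        current = fit
    return StepwiseResult(selected=selected, entry_p_values=entry_ps, final_fit=current)


# ---------------------------------------------------------------------------
# report layer
# ---------------------------------------------------------------------------

METRIC_NAMES = ["mode", "median", "mean", "p75", "p90", "p95", "max", "sd"]
DURATION_CATEGORIES = ["short", "medium", "long"]


def _metric_columns(table: pd.DataFrame, categories: Sequence[str]) -> dict:
    """Map category -> available metric columns named ``<metric>_<category>``."""
    out = {}
    for cat in categories:
        cols = [f"{m}_{cat}" for m in METRIC_NAMES if f"{m}_{cat}" in table.columns]
        if cols:
            out[cat] = cols
    return out


def _nested_report(table: pd.DataFrame, outcome: str, kind: str) -> pd.DataFrame:
    fit_fn = fit_logistic if kind == "logistic" else fit_linear
    score_name = "auc" if kind == "logistic" else "adj_r2"
    by_cat = _metric_columns(table, DURATION_CATEGORIES)
    if not by_cat:
        raise ValueError("no speed-metric columns found in the cohort table")
    rows = []
    for cat, cols in by_cat.items():
        for col in cols:
            data = table.dropna(subset=[col])
            try:
                fit_a = fit_fn(data, ModelSpec(outcome))
                fit_b = fit_fn(data, ModelSpec(outcome, (col,)))
                cmpres = compare_nested(fit_a, fit_b)
            except (SeparationError, RuntimeError, ValueError):
                # not computable on this subset (e.g. separation at small n)
                rows.append(
                    {
                        "duration": cat,
                        "metric": col.rsplit("_", 1)[0],
                        "n": len(data),
                        f"{score_name}_a": np.nan,
                        f"{score_name}_b": np.nan,
                        "lr": np.nan,
                        "p_value": np.nan,
                        "aic_a": np.nan,
                        "aic_b": np.nan,
                        "bic_a": np.nan,
                        "bic_b": np.nan,
                        "sig_0.05": False,
                        "sig_0.001": False,
                    }
                )
                continue
            rows.append(
                {
                    "duration": cat,
                    "metric": col.rsplit("_", 1)[0],
                    "n": fit_b.n,
                    f"{score_name}_a": getattr(fit_a, score_name),
                    f"{score_name}_b": getattr(fit_b, score_name),
                    "lr": cmpres.lr_stat,
                    "p_value": cmpres.p_value,
                    "aic_a": fit_a.aic,
                    "aic_b": fit_b.aic,
                    "bic_a": fit_a.bic,
                    "bic_b": fit_b.bic,
                    "sig_0.05": cmpres.p_value < ALPHA_NOMINAL,
                    "sig_0.001": cmpres.p_value < ALPHA_HEADLINE,
                }
            )
    return pd.DataFrame(rows)


def run_frailty_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Model A vs model B (one speed metric at a time) for frailty status.

    One row per (duration category, metric) with model B's AUC, the LR
    statistic and p-value, and both models' AIC/BIC.
    """
    return _nested_report(table, "frail", "logistic")


def run_grip_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Same layout as the frailty report, for handgrip strength (linear)."""
    return _nested_report(table, "grip_kg", "linear")


def sensitivity_exclude_runners(
    table: pd.DataFrame, max_walk_speed: float = 2.5
) -> Tuple[pd.DataFrame, int]:
    """Drop subjects whose all-bout 95th-percentile speed exceeds the
    maximum plausible walking speed (likely runners); returns the filtered
    table and the exclusion count."""
    if "p95_all" not in table.columns:
        raise ValueError("table must contain the all-bout p95 column 'p95_all'")
    keep = ~(table["p95_all"] > max_walk_speed)
    return table[keep].copy(), int((~keep).sum())


def sensitivity_age65(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict the cohort to participants aged 65 years and over."""
    return table[table["age"] >= 65].copy()
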