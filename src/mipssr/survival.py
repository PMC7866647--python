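"""Survival statistics for score development and validation.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fits are delegated to ``lifelines``; L1-penalized (LASSO) Cox paths ride on
``scikit-survival``'s coordinate-descent solver with a cross-validation
wrapper implemented here.  The time-dependent ROC uses the Kaplan-Meier
based cumulative-case / dynamic-control estimator, implemented directly
because no installed package provides that particular estimator.

Times are in months; events are coded 1 = death, 0 = censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxFit",
    "CoxFitError",
    "LassoPath",
    "LogrankResult",
    "ROCResult",
    "SurvivalCurve",
    "cox_fit",
    "km_estimate",
    "lasso_cox",
    "logrank_test",
    "td_roc",
    "uni_cox_screen",
    "validate_groups",
]


class CoxFitError(RuntimeError):
    """A Cox model could not be fit (no events, degenerate design, ...)."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) and at-risk counts at observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    median: float | None  # None = not reached within follow-up
    max_followup: float

    @property
    def median_label(self) -> str:
        if self.median is not None:
            return f"{self.median:g}"
        return f">{self.max_followup:g}"


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival data")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("survival times must be finite and > 0")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return t, e.astype(int)


def km_estimate(time, event) -> SurvivalCurve:
    """Kaplan-Meier survival curve with the median read off the curve.

    The median is the first event time at which S(t) drops to 0.5 or
    below; when the curve never reaches 0.5 the median is not reached and
    ``median_label`` renders it as ``">{max follow-up}"``.
    """
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    median = None
    drops = times[(surv <= 0.5) & (table["observed"].to_numpy() > 0)]
    if drops.size:
        median = float(drops[0])
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        n=int(t.size),
        n_events=int(e.sum()),
        median=median,
        max_followup=float(t.max()),
    )


def _km_at(time: np.ndarray, event: np.ndarray, horizon: float) -> float:
    """S(horizon) by the product-limit formula (internal fast path)."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    s = 1.0
    n_at_risk = t.size
    i = 0
    while i < t.size and t[i] <= horizon:
        j = i
        d = 0
        while j < t.size and t[j] == t[i]:
            d += e[j]
            j += 1
        if d:
            s *= 1.0 - d / n_at_risk
        n_at_risk -= j - i
        i = j
    return s


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank_test(groups: list[tuple]) -> LogrankResult:
    """k-sample log-rank test over pooled event times.

    ``groups`` is a list of ``(time, event)`` pairs, one per group; the
    statistic is chi-square with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t, e = _as_arrays(t, e)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return LogrankResult(
        chi2=float(res.test_statistic), df=len(groups) - 1, p=float(res.p_value)
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxFit:
    coef: pd.Series
    se: pd.Series
    hr: pd.Series
    p: pd.Series
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def cox_fit(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
    *,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit on the partial likelihood.

    Ties are handled by Efron's method (the field's default); Breslow is
    available via ``ties="breslow"`` using a direct Newton-type
    maximization of the Breslow partial likelihood.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    if not covariates:
        raise ValueError("no covariates to fit")
    sub = df[[duration_col, event_col, *covariates]].copy()
    if sub.isna().any().any():
        raise ValueError("missing values in the fitting frame")
    t, e = _as_arrays(sub[duration_col], sub[event_col])
    if e.sum() < 1:
        raise CoxFitError("cannot fit a Cox model with zero events")
    degenerate = [c for c in covariates if sub[c].nunique() < 2]
    if degenerate:
        raise CoxFitError(f"constant covariate(s): {degenerate}")

    if ties == "breslow":
        return _cox_fit_breslow(sub, duration_col, event_col, covariates, t, e)
    if ties != "efron":
        raise ValueError(f"unknown tie-handling method {ties!r}")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                sub,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-9},
            )
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise CoxFitError(f"Cox fit did not converge: {exc}") from exc
    summ = cph.summary
    return CoxFit(
        coef=cph.params_.rename(None),
        se=summ["se(coef)"].rename(None),
        hr=summ["exp(coef)"].rename(None),
        p=summ["p"].rename(None),
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def _neg_log_partial_likelihood(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> float:
    """Negative log partial likelihood (Breslow or Efron tie handling)."""
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    t, e, eta = time[order], event[order], eta[order]
    w = np.exp(eta)
    # risk-set sums: sum of w over subjects with time >= t_i
    rev_cum = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = slice(i, j)
        d = int(e[ev].sum())
        if d:
            risk = rev_cum[i]
            tied_w = w[ev][e[ev] == 1]
            ll += float(eta[ev][e[ev] == 1].sum())
            if ties == "breslow":
                ll -= d * np.log(risk)
            else:  # efron
                s_d = tied_w.sum()
                for k in range(d):
                    ll -= np.log(risk - (k / d) * s_d)
        i = j
    return -ll


def _fd_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian (observed information at the MLE)."""
    p = x.size
    H = np.empty((p, p))
    steps = h * (1.0 + np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def _cox_fit_breslow(sub, duration_col, event_col, covariates, t, e) -> CoxFit:
    from scipy.optimize import minimize

    X = sub[covariates].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    res = minimize(
        _neg_log_partial_likelihood,
        np.zeros(X.shape[1]),
        args=(Xc, t, e, "breslow"),
        method="BFGS",
        options={"gtol": 1e-8},
    )
    if not res.success and res.status != 2:  # 2 = precision loss near optimum
        raise CoxFitError(f"Breslow Cox fit did not converge: {res.message}")
    hess = _fd_hessian(
        lambda b: _neg_log_partial_likelihood(b, Xc, t, e, "breslow"), res.x
    )
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise CoxFitError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    from scipy.stats import norm

    z = res.x / se
    return CoxFit(
        coef=pd.Series(res.x, index=covariates).rename(None),
        se=pd.Series(se, index=covariates).rename(None),
        hr=pd.Series(np.exp(res.x), index=covariates).rename(None),
        p=pd.Series(2 * norm.sf(np.abs(z)), index=covariates).rename(None),
        log_likelihood=-float(res.fun),
        converged=True,
        n=int(t.size),
        n_events=int(e.sum()),
    )


# ---------------------------------------------------------------------------
# LASSO-penalized Cox


@dataclass(frozen=True)
class LassoPath:
    lambdas: np.ndarray
    coef_path: pd.DataFrame  # covariates x lambdas, original scale
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_min: float
    coef_min: pd.Series
    selected: tuple[str, ...] = field(default=())


def lasso_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    *,
    lambdas=None,
    n_lambdas: int = 100,
    k_folds: int = 10,
    seed: int,
) -> LassoPath:
    """L1-penalized Cox path with k-fold cross-validated lambda selection.

    Covariates are standardized internally; reported coefficients are on
    the original scale.  The lambda grid defaults to ``n_lambdas``
    log-spaced values from the smallest all-zero penalty down four decades.
    ``lambda_min`` minimizes the mean cross-validated partial-likelihood
    deviance (-2 log PL on the held-out fold); the selected covariates are
    those with nonzero coefficients at ``lambda_min``.  Folds are
    stratified by event status and ``seed`` is required so reruns are
    reproducible.  A requested lambda of 0 is mapped to a numerically
    negligible penalty (the unpenalized limit).
    """
    if k_folds < 3:
        raise ValueError("use at least 3 cross-validation folds")
    t, e = _as_arrays(df[duration_col], df[event_col])
    X = df[list(covariates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in covariates")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(covariates, sd) if s == 0]
        raise CoxFitError(f"constant covariate(s): {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    if lambdas is None:
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=1e-4
        )
        probe.fit(Xs, y)
        grid = np.asarray(probe.alphas_, dtype=float)
    else:
        grid = np.asarray(sorted(set(float(l) for l in lambdas), reverse=True))
        floor = max(grid.max(), 1.0) * 1e-9
        grid = np.where(grid <= 0, floor, grid)
        grid = np.unique(grid)[::-1]

    if int(e.sum()) < k_folds:
        raise CoxFitError("too few events for stratified cross-validation")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    dev = np.full((k_folds, grid.size), np.nan)
    for f, (tr, te) in enumerate(skf.split(Xs, e)):
        if e[te].sum() == 0 or e[tr].sum() == 0:
            raise CoxFitError(f"fold {f} has no events; reduce k_folds")
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=grid, tol=1e-9, fit_baseline_model=False
        )
        model.fit(Xs[tr], y[tr])
        fitted = np.asarray(model.alphas_, dtype=float)
        for a, lam in enumerate(grid):
            idx = int(np.argmin(np.abs(fitted - lam)))
            beta = model.coef_[:, idx]
            dev[f, a] = 2.0 * _neg_log_partial_likelihood(
                beta, Xs[te], t[te], e[te], ties="breslow"
            )
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(k_folds)
    lambda_min = float(grid[int(np.argmin(cv_mean))])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=grid, tol=1e-9, fit_baseline_model=False
    )
    final.fit(Xs, y)
    fitted = np.asarray(final.alphas_, dtype=float)
    coef_std = np.column_stack(
        [final.coef_[:, int(np.argmin(np.abs(fitted - lam)))] for lam in grid]
    )
    coef_orig = coef_std / sd[:, None]
    coef_path = pd.DataFrame(coef_orig, index=list(covariates), columns=grid)
    coef_min = coef_path[lambda_min]
    if isinstance(coef_min, pd.DataFrame):  # duplicate lambda labels
        coef_min = coef_min.iloc[:, 0]
    selected = tuple(c for c in covariates if abs(coef_min[c]) > 0)
    return LassoPath(
        lambdas=grid,
        coef_path=coef_path,
        cv_deviance=cv_mean,
        cv_deviance_se=cv_se,
        lambda_min=lambda_min,
        coef_min=coef_min,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# Time-dependent ROC


@dataclass(frozen=True)
class ROCResult:
    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def td_roc(marker, time, event, horizon: float) -> ROCResult:
    """Time-dependent ROC at a fixed horizon (cumulative case / dynamic
    control, Kaplan-Meier estimator).

    Cases are subjects with an event by the horizon, controls those still
    event-free; the joint probability P(M > c, T > t) is estimated through
    the Kaplan-Meier curve of the subgroup with marker above the cutoff,
    which accommodates censoring before the horizon.  AUC is the
    trapezoidal area under sensitivity vs. 1-specificity.
    """
    m = np.asarray(marker, dtype=float)
    t, e = _as_arrays(time, event)
    if m.size != t.size:
        raise ValueError("marker and survival data differ in length")
    if np.isnan(m).any():
        raise ValueError("marker contains missing values")
    if not 0 < horizon <= t.max():
        raise ValueError(
            f"horizon {horizon} outside observed follow-up (0, {t.max():g}]"
        )
    s_t = _km_at(t, e, horizon)
    if s_t >= 1.0:
        raise ValueError("no cases (events) observed by the horizon")
    if s_t <= 0.0:
        raise ValueError("no controls remain event-free at the horizon")

    cutoffs = np.unique(m)
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        above = m > c
        p_above = above.mean()
        joint = p_above * _km_at(t[above], e[above], horizon) if p_above else 0.0
        sens[i] = (p_above - joint) / (1.0 - s_t)
        spec[i] = (s_t - joint) / s_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ROCResult(
        horizon=float(horizon),
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


# ---------------------------------------------------------------------------
# Screens and group validation


def uni_cox_screen(
    df: pd.DataFrame, duration_col: str, event_col: str, factors: list[str]
) -> pd.DataFrame:
    """One univariate Cox fit per factor; failures are flagged, not fatal.

    Returns a table (one row per factor) with the log hazard ratio, HR,
    95% CI, Wald p-value and a status column, sorted by p-value.
    """
    rows = []
    for factor in factors:
        try:
            fit = cox_fit(df, duration_col, event_col, [factor])
            coef = float(fit.coef.iloc[0])
            se = float(fit.se.iloc[0])
            rows.append(
                {
                    "factor": factor,
                    "coef": coef,
                    "hr": float(fit.hr.iloc[0]),
                    "ci_low": float(np.exp(coef - 1.959964 * se)),
                    "ci_high": float(np.exp(coef + 1.959964 * se)),
                    "p": float(fit.p.iloc[0]),
                    "status": "ok",
                }
            )
        except (CoxFitError, ValueError) as exc:
            rows.append(
                {
                    "factor": factor,
                    "coef": np.nan,
                    "hr": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "status": f"failed: {exc}",
                }
            )
    table = pd.DataFrame(rows).sort_values("p", na_position="last")
    return table.reset_index(drop=True)


def validate_groups(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    group_col: str,
    *,
    horizon: float | None = None,
    markers: dict[str, str] | None = None,
) -> dict:
    """Per-group Kaplan-Meier medians, the log-rank test, and optional
    time-dependent AUCs for named marker columns.

    ``horizon`` defaults to the cohort's median follow-up time.
    """
    if horizon is None:
        horizon = float(np.median(df[duration_col]))
    groups, medians = [], {}
    for label, sub in df.groupby(group_col, observed=True, sort=True):
        curve = km_estimate(sub[duration_col], sub[event_col])
        medians[str(label)] = curve.median_label
        groups.append((sub[duration_col].to_numpy(), sub[event_col].to_numpy()))
    lr = logrank_test(groups) if len(groups) >= 2 else None
    out = {
        "horizon_months": horizon,
        "median_os_by_group": medians,
        "logrank": None
        if lr is None
        else {"chi2": lr.chi2, "df": lr.df, "p": lr.p},
    }
    if markers:
        out["auc"] = {
            name: td_roc(df[col], df[duration_col], df[event_col], horizon).auc
            for name, col in markers.items()
        }
    return out
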