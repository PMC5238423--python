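"""Trend and model-selection machinery: AICc, OLS trend fits, exact-ML AR(1)
error regression, random-intercept linear mixed models, and detrending.

All models inside one comparison set are fitted by maximum likelihood (not
REML) so AICc values are comparable across fixed-effect structures. Parameter
counts include every estimated quantity: fixed effects, the residual
variance, the AR(1) coefficient where present, and the random-intercept
variance where present.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion
    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _safe_aicc(loglik: float, k: int, n: int) -> float:
    """AICc, or NaN when the correction term is undefined (n <= k + 1); a
    NaN row sinks to the bottom of a model table instead of aborting the
    comparison."""
    try:
        return aicc(loglik, k, n)
    except ValueError:
        return float("nan")


def detrend(values: Sequence[float], year: Sequence[float]) -> np.ndarray:
    """OLS residuals of ``values`` on ``year`` (the detrended series)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(year, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows to detrend")
    if np.ptp(x) == 0:
        raise ValueError("year column is constant; cannot detrend")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


# ----------------------------------------------------------------------
# model-table plumbing

@dataclass
class FittedModel:
    label: str
    k: int
    n: int
    loglik: float
    aicc: float
    converged: bool
    params: pd.Series
    bse: pd.Series
    extra: dict


def model_table(models: Iterable[FittedModel]) -> pd.DataFrame:
    """AICc-ranked comparison table; ``delta_aicc`` is 0 for the best row.
    Rows with non-finite AICc (failed fits) sink to the bottom."""
    rows = []
    for m in models:
        rows.append(dict(model=m.label, k=m.k, n=m.n, loglik=m.loglik,
                         aicc=m.aicc, converged=m.converged))
    tab = pd.DataFrame(rows).sort_values(["aicc", "model"], kind="stable",
                                         na_position="last").reset_index(drop=True)
    best = tab["aicc"].min(skipna=True)
    tab["delta_aicc"] = tab["aicc"] - best
    return tab


def coefficients_frame(models: Iterable[FittedModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        for name in m.params.index:
            rows.append(dict(model=m.label, term=name,
                             estimate=float(m.params[name]),
                             se=float(m.bse.get(name, np.nan))))
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# OLS and AR(1)-error regression, exact ML

def _ols_ml(y: np.ndarray, X: np.ndarray, names: List[str], label: str) -> FittedModel:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    s2 = max(ssr / n, 1e-300)
    llf = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    k = X.shape[1] + 1
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * ssr / max(n - X.shape[1], 1), 0.0))
    return FittedModel(label=label, k=k, n=n, loglik=llf, aicc=_safe_aicc(llf, k, n),
                       converged=True, params=pd.Series(beta, index=names),
                       bse=pd.Series(se, index=names), extra={"sigma2": s2})


def _ar1_ml(y: np.ndarray, X: np.ndarray, names: List[str], label: str) -> FittedModel:
    """Exact maximum likelihood for a regression with AR(1) errors
    (stationary initial condition, Prais-Winsten transform), profiling out
    the coefficients and innovation variance and optimising the
    autocorrelation rho numerically."""
    n = len(y)

    def profile(rho):
        w = np.sqrt(1.0 - rho * rho)
        ys = np.concatenate([[w * y[0]], y[1:] - rho * y[:-1]])
        Xs = np.vstack([w * X[:1], X[1:] - rho * X[:-1]])
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        ssr = float(resid @ resid)
        s2 = max(ssr / n, 1e-300)
        llf = (-0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
               + 0.5 * np.log(1.0 - rho * rho))
        return llf, beta, Xs, ssr

    res = minimize_scalar(lambda r: -profile(r)[0], bounds=(-0.98, 0.98),
                          method="bounded", options={"xatol": 1e-8})
    rho = float(res.x)
    llf, beta, Xs, ssr = profile(rho)
    k = X.shape[1] + 2  # + innovation variance + rho
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * ssr / max(n - X.shape[1], 1), 0.0))
    return FittedModel(label=label, k=k, n=n, loglik=llf, aicc=_safe_aicc(llf, k, n),
                       converged=bool(res.success),
                       params=pd.Series(beta, index=names),
                       bse=pd.Series(se, index=names), extra={"rho": rho})


# ----------------------------------------------------------------------
# design-matrix construction

_BASE_TERMS = {"year", "age", "temp", "prec", "greenup", "dgreenup", "ddate"}


def build_design(frame: pd.DataFrame, terms: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    """Design matrix with intercept for the given terms. ``age`` is coded
    adult=1 / immature=0; ``a:b`` denotes a product interaction."""
    cols = [np.ones(len(frame))]
    names = ["const"]

    def col(term):
        if term == "age":
            return (frame["age_class"].astype(str) == "adult").to_numpy(dtype=float)
        return frame[term].to_numpy(dtype=float)

    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(col(a) * col(b))
        else:
            cols.append(col(term))
        names.append(term)
    return np.column_stack(cols), names


# ----------------------------------------------------------------------
# cross-sectional trend models (LM vs AR(1)-error LM)

def fit_trend_ols(values: Sequence[float], year: Sequence[float],
                  label_prefix: str = "") -> List[FittedModel]:
    """Intercept-only vs year-slope OLS (ML likelihoods); the basic trend test."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(year, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows for a trend comparison")
    null = _ols_ml(y, np.ones((n, 1)), ["const"], f"{label_prefix}null")
    slope = _ols_ml(y, np.column_stack([np.ones(n), x]), ["const", "year"],
                    f"{label_prefix}year")
    return [null, slope]


def fit_cross_sectional(frame: pd.DataFrame, response: str = "date") -> Tuple[pd.DataFrame, pd.DataFrame, Dict]:
    """Cross-sectional (one row per year) trend analysis: intercept-only and
    year-slope means, each with i.i.d. and with AR(1) errors; all four models
    in one AICc table. Returns (table, coefficients, headline) where headline
    carries the year slope from the best-supported error structure."""
    df = frame.sort_values("year")
    y = df[response].to_numpy(dtype=float)
    x = df["year"].to_numpy(dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 yearly rows")
    X_null = np.ones((n, 1))
    X_year = np.column_stack([np.ones(n), x])
    models = [
        _ols_ml(y, X_null, ["const"], "null_iid"),
        _ols_ml(y, X_year, ["const", "year"], "year_iid"),
        _ar1_ml(y, X_null, ["const"], "null_ar1"),
        _ar1_ml(y, X_year, ["const", "year"], "year_ar1"),
    ]
    tab = model_table(models)
    by_label = {m.label: m for m in models}

    def _a(label):  # NaN (undefined small-sample AICc) loses any comparison
        v = by_label[label].aicc
        return np.inf if np.isnan(v) else v

    ar1_preferred = (min(_a("null_ar1"), _a("year_ar1"))
                     < min(_a("null_iid"), _a("year_iid")))
    best_year = by_label["year_ar1" if ar1_preferred else "year_iid"]
    headline = dict(slope=float(best_year.params["year"]),
                    slope_se=float(best_year.bse["year"]),
                    error_structure="ar1" if ar1_preferred else "iid",
                    year_beats_null=bool(
                        _a(best_year.label) < _a("null_ar1" if ar1_preferred else "null_iid")))
    return tab, coefficients_frame(models), headline


# ----------------------------------------------------------------------
# random-intercept linear mixed models

def fit_random_intercept(frame: pd.DataFrame, terms: Sequence[str], response: str,
                         label: str | None = None, groups: str = "ID") -> FittedModel:
    """ML fit of ``response ~ terms + (1 | groups)`` via statsmodels MixedLM.
    k counts fixed effects + random-intercept variance + residual variance."""
    X, names = build_design(frame, terms)
    y = frame[response].to_numpy(dtype=float)
    g = frame[groups].to_numpy()
    label = label or ("1" if not terms else "+".join(terms))
    n = len(y)
    k = X.shape[1] + 2
    res = None
    err = None
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=g).fit(reml=False, method=method,
                                                     maxiter=2000)
            if np.isfinite(res.llf):
                break
        except Exception as exc:  # retry, then boundary fallback below
            err = exc
            res = None
    if res is not None and np.isfinite(res.llf):
        llf = float(res.llf)
        converged = bool(res.converged)
        params = pd.Series(np.asarray(res.fe_params, dtype=float), index=names)
        bse = pd.Series(np.asarray(res.bse_fe, dtype=float), index=names)
        re_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else np.nan
        extra = {"re_var": re_var, "resid_var": float(res.scale)}
    else:
        # optimizer failure at the zero-variance boundary: the ML solution
        # degenerates to OLS with re_var = 0 (k unchanged for comparability)
        ols = _ols_ml(y, X, names, label)
        llf, converged = ols.loglik, True
        params, bse = ols.params, ols.bse
        extra = {"re_var": 0.0, "resid_var": ols.extra["sigma2"],
                 "boundary_fallback": True, "error": str(err) if err else None}
    return FittedModel(label=label, k=k, n=n, loglik=llf, aicc=_safe_aicc(llf, k, n),
                       converged=converged, params=params, bse=bse, extra=extra)


def fit_lmm_set(frame: pd.DataFrame, covariates: Sequence[str],
                response: str = "date") -> Tuple[pd.DataFrame, pd.DataFrame, List[FittedModel]]:
    """Candidate random-intercept model set for the longitudinal analysis.

    Year is in every candidate (the migration dates carry a pronounced year
    trend); the set is year-only, year+age, year+each covariate,
    year+age+each covariate, and — when both climate covariates are supplied
    — the full model with their product interaction.
    """
    if len(frame) < 10 or frame["ID"].nunique() < 5:
        raise ValueError("need >=10 bird-years across >=5 individuals")
    cand: List[List[str]] = [["year"], ["year", "age"]]
    for c in covariates:
        cand.append(["year", c])
        cand.append(["year", "age", c])
    if len(covariates) == 2:
        a, b = covariates
        cand.append(["year", "age", a, b, f"{a}:{b}"])
    models = [fit_random_intercept(frame, terms, response) for terms in cand]
    return model_table(models), coefficients_frame(models), models


def detrended_greenup_models(frame: pd.DataFrame, response: str = "ddate") -> Tuple[pd.DataFrame, pd.DataFrame, List[FittedModel]]:
    """Spurious-correlation check: after removing the shared year trend from
    both series, is the detrended migration date still related to the
    detrended green-up date? Candidate set: intercept-only, dgreenup,
    dgreenup+age, dgreenup+age+dgreenup:age, all with a random intercept."""
    for col in ("ddate", "dgreenup"):
        if col not in frame.columns:
            raise ValueError(f"frame lacks detrended column {col!r}")
    cand = [[], ["dgreenup"], ["dgreenup", "age"],
            ["dgreenup", "age", "dgreenup:age"]]
    models = [fit_random_intercept(frame, terms, response,
                                   label="1" if not terms else "+".join(terms))
              for terms in cand]
    return model_table(models), coefficients_frame(models), models
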