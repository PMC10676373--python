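"""Time-to-diagnosis trend analysis for prospective cases.

Two stages: (1) covariate-adjusted residualization of case expression with
a study random intercept (REML linear mixed model), (2) unpenalized
natural-cubic-spline smoothing of the residuals against years to diagnosis
(basis dimension 2 by default: one interior knot at the median time).  A
formal elevation flag compares the mean fitted value inside a window close
to diagnosis with the mean outside it, in units of pooled pointwise
standard error.

The time axis runs from 0 at diagnosis backwards into the past.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .preprocess import scale_covariate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage 1: mixed-model residualization


def _case_design(ann: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(ann))]
    if ann["age_years"].nunique() > 1:
        cols.append(scale_covariate(ann["age_years"].to_numpy(dtype=float)))
    if ann["sex"].nunique() > 1:
        cols.append((ann["sex"] == "M").astype(float).to_numpy())
    smoking = ann["smoking7"].astype(str)
    levels = sorted(smoking.unique())
    for lev in levels[1:]:
        v = (smoking == lev).astype(float).to_numpy()
        if 0 < v.sum() < len(v):
            cols.append(v)
    return np.column_stack(cols)


def _reml_random_intercept(y: np.ndarray, X: np.ndarray, clusters: np.ndarray):
    """Profiled REML for a single Gaussian random intercept.

    With one variance ratio lambda = sigma2_u / sigma2_e the per-cluster
    covariance V_j = I + lambda 11' inverts in closed form, so the REML
    criterion reduces to a bounded one-dimensional optimization in
    log lambda.  Returns (beta, BLUP u per observation, sigma2_u, sigma2_e).
    """
    n, p = X.shape
    levels = pd.unique(clusters)
    idx = [np.where(clusters == lev)[0] for lev in levels]
    sizes = np.array([len(i) for i in idx], dtype=float)

    def gls(lam):
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        for i, nj in zip(idx, sizes):
            Xj, yj = X[i], y[i]
            f = lam / (1.0 + lam * nj)
            xs, ys = Xj.sum(axis=0), yj.sum()
            xtvx += Xj.T @ Xj - f * np.outer(xs, xs)
            xtvy += Xj.T @ yj - f * xs * ys
        beta = np.linalg.solve(xtvx, xtvy)
        r = y - X @ beta
        rss = 0.0
        for i, nj in zip(idx, sizes):
            rj = r[i]
            f = lam / (1.0 + lam * nj)
            rss += rj @ rj - f * rj.sum() ** 2
        return beta, r, rss, xtvx

    def neg_reml(loglam):
        lam = np.exp(loglam)
        _, _, rss, xtvx = gls(lam)
        s2e = rss / (n - p)
        logdet_v = np.sum(np.log1p(lam * sizes))
        _, logdet_x = np.linalg.slogdet(xtvx)
        return 0.5 * ((n - p) * np.log(s2e) + logdet_v + logdet_x)

    res = optimize.minimize_scalar(neg_reml, bounds=(-25.0, 15.0), method="bounded")
    lam = float(np.exp(res.x))
    if neg_reml(-25.0) <= res.fun:  # boundary: no between-cluster variance
        lam = 0.0
    beta, r, rss, _ = gls(lam)
    s2e = rss / (n - p)
    u = np.zeros(n)
    for i, nj in zip(idx, sizes):
        u[i] = lam * nj / (1.0 + lam * nj) * r[i].mean()  # BLUP shrinkage
    return beta, u, lam * s2e, s2e


def lmm_residuals(values, annotation: pd.DataFrame, return_components: bool = False):
    """Conditional residuals of a study-random-intercept REML mixed model.

    The fixed part adjusts for scaled age, sex and the seven-category
    smoking variable.  With a single study the model degrades to ordinary
    least squares (logged).
    """
    ann = annotation.reset_index(drop=True)
    y = np.asarray(values, dtype=float)
    X = _case_design(ann)
    if len(y) <= X.shape[1] + 2:
        X = X[:, :1]  # too few cases to adjust: intercept only
    studies = ann["study"].astype(str).to_numpy()

    if len(pd.unique(studies)) < 2:
        logger.info("single study: OLS residualization fallback")
        fit = sm.OLS(y, X).fit()
        resid = y - fit.fittedvalues
        if return_components:
            return resid, {"sigma2_study": 0.0, "sigma2_resid": float(fit.scale)}
        return resid

    beta, u, s2u, s2e = _reml_random_intercept(y, X, studies)
    resid = y - X @ beta - u
    if return_components:
        return resid, {"sigma2_study": s2u, "sigma2_resid": s2e}
    return resid


# ---------------------------------------------------------------------------
# stage 2: natural cubic spline smoothing


def natural_cubic_basis(x: np.ndarray, df: int, knots=None, boundary=None):
    """Natural cubic spline basis with ``df`` columns (intercept excluded).

    df = 1 is a plain linear term; df >= 2 adds df - 1 interior knots at
    time quantiles between boundary knots at the data range.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if boundary is None:
        boundary = (x.min(), x.max())
    if df == 1:
        return x[:, None], np.array([]), boundary
    if knots is None:
        qs = np.linspace(0, 1, df + 1)[1:-1]
        knots = np.quantile(x, qs)
    knots = np.atleast_1d(np.asarray(knots, dtype=float))
    allk = np.concatenate([[boundary[0]], knots, [boundary[1]]])
    K = allk.size

    def d(k, xx):
        num = np.maximum(xx - allk[k], 0) ** 3 - np.maximum(xx - allk[K - 1], 0) ** 3
        return num / (allk[K - 1] - allk[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols), knots, boundary


@dataclass
class TrendFit:
    df: int
    knots: np.ndarray
    boundary: tuple
    coefficients: np.ndarray
    grid: np.ndarray           # time grid, 0 = diagnosis
    fitted: np.ndarray
    se: np.ndarray
    n_cases: int
    label: str = "all"


def spline_trend(residuals, time_to_dx, df: int = 2, n_grid: int = 101, label: str = "all") -> TrendFit:
    """Least-squares natural-cubic-spline fit of residuals on time to
    diagnosis with pointwise standard errors from the hat matrix."""
    y = np.asarray(residuals, dtype=float)
    t = np.asarray(time_to_dx, dtype=float)
    if (t <= 0).any():
        raise ValueError("times to diagnosis must be > 0")
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct times")
    if y.size < df + 2:
        raise ValueError(f"need at least df + 2 = {df + 2} cases")
    B, knots, boundary = natural_cubic_basis(t, df)
    X = np.column_stack([np.ones(len(t)), B])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(t) - X.shape[1]
    s2 = (resid ** 2).sum() / max(dof, 1)
    xtx_inv = np.linalg.pinv(X.T @ X)

    grid = np.linspace(0.0, t.max(), n_grid)
    gx = np.clip(grid, boundary[0], boundary[1])  # clamp outside data range
    Bg, _, _ = natural_cubic_basis(gx, df, knots=knots if df > 1 else None, boundary=boundary)
    Xg = np.column_stack([np.ones(len(gx)), Bg])
    fitted = Xg @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, xtx_inv, Xg), 0.0) * s2)
    return TrendFit(df, knots, boundary, beta, grid, fitted, se, len(t), label)


def detect_window_elevation(trend: TrendFit, window_years: float = 2.0, k_se: float = 2.0) -> dict:
    """Flag elevated expression close to diagnosis.

    True iff the mean fitted value on [0, window] exceeds the mean on
    (window, max] by more than ``k_se`` pooled pointwise standard errors.
    The comparison is one-sided; the sign of the difference is reported
    either way.
    """
    if window_years >= trend.grid.max():
        raise ValueError("window must lie inside the observed time range")
    inside = trend.grid <= window_years
    outside = ~inside
    mean_in = trend.fitted[inside].mean()
    mean_out = trend.fitted[outside].mean()
    pooled_se = float(np.sqrt(np.mean(trend.se ** 2)))
    diff = float(mean_in - mean_out)
    flag = diff > k_se * pooled_se
    return {
        "flag": bool(flag),
        "difference": diff,
        "pooled_se": pooled_se,
        "direction": "positive" if diff > 0 else ("negative" if diff < 0 else "flat"),
        "window_years": window_years,
        "k_se": k_se,
        "label": trend.label,
    }


def stagewise_trends(values, annotation: pd.DataFrame, df: int = 2) -> dict[str, TrendFit]:
    """Trend fits per stage group plus an overall fit on all cases."""
    ann = annotation.reset_index(drop=True)
    cases = ann[(ann["case_status"] == "case") & ann["time_to_dx_years"].notna()].reset_index()
    vals = np.asarray(values, dtype=float)
    if len(vals) == len(ann):
        vals = vals[cases["index"].to_numpy()]
    elif len(vals) != len(cases):
        raise ValueError("values must align with annotation rows or with cases")
    fits: dict[str, TrendFit] = {}
    groups = [(s, cases["stage"] == s) for s in ("early", "middle", "late")]
    groups.append(("all", pd.Series(True, index=cases.index)))
    for label, mask in groups:
        n = int(mask.sum())
        if n < df + 2:
            if label != "all":
                warnings.warn(f"stage {label!r} has {n} cases (< df + 2); skipped", stacklevel=2)
                continue
            raise ValueError("too few cases for the overall trend fit")
        sub = cases[mask.to_numpy()]
        resid = lmm_residuals(vals[mask.to_numpy()], sub)
        try:
            fits[label] = spline_trend(resid, sub["time_to_dx_years"].to_numpy(dtype=float), df=df, label=label)
        except ValueError as exc:
            warnings.warn(f"trend fit for {label!r} skipped: {exc}", stacklevel=2)
    return fits


def write_trends(fits: dict[str, TrendFit], path) -> None:
    frames = [
        pd.DataFrame({"time": f.grid, "fitted": f.fitted, "se": f.se, "stage": label})
        for label, f in fits.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
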