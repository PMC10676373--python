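"""Prospective case-control validation of candidate genes.

Gene-wise logistic models with a study-level random intercept (Laplace-
approximated maximum likelihood, the convention of standard mixed-model
software), the two-year time-to-diagnosis restriction, and the exact
binomial test of effect-direction concordance between cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .preprocess import scale_covariate

logger = logging.getLogger(__name__)


@dataclass
class ORResult:
    gene: str
    comparison: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    window_years: float | None
    model_type: str            # "random-intercept" or "fixed-study"
    coefficient: float = np.nan
    se: float = np.nan
    sigma_study: float = np.nan
    separation: bool = False
    n_cases: int = 0
    n_controls: int = 0


# ---------------------------------------------------------------------------
# Laplace-approximated logistic random-intercept model


def _cluster_laplace(eta, y, sigma2):
    """Laplace-approximated log marginal likelihood of one cluster.

    Finds the mode of the random intercept by Newton iteration (the
    integrand is log-concave) and applies the second-order expansion.
    """
    u = 0.0
    for _ in range(100):
        p = special.expit(eta + u)
        g = np.sum(y - p) - u / sigma2
        h = -np.sum(p * (1 - p)) - 1.0 / sigma2
        step = -g / h
        u += step
        if abs(step) < 1e-10:
            break
    p = special.expit(eta + u)
    loglik = np.sum(y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1)))
    g2 = np.sum(p * (1 - p)) + 1.0 / sigma2
    # log ∫ exp(loglik(u) - u^2/(2σ²)) / sqrt(2πσ²) du
    return loglik - u ** 2 / (2 * sigma2) - 0.5 * np.log(sigma2 * g2)


def _mixed_nll(params, X, y, cluster_idx):
    beta = params[:-1]
    sigma2 = np.exp(2.0 * params[-1])
    eta = X @ beta
    nll = 0.0
    for idx in cluster_idx:
        nll -= _cluster_laplace(eta[idx], y[idx], sigma2)
    return nll


def _numeric_hessian(f, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_logistic_random_intercept(X: np.ndarray, y: np.ndarray, cluster: np.ndarray):
    """ML fit of a logistic model with a Gaussian cluster random intercept.

    Returns (beta, se, sigma_study, model_type).  When the random-intercept
    standard deviation collapses to the zero boundary, or only one cluster
    is present, the model falls back to fixed cluster indicators / plain
    logistic regression.
    """
    levels = pd.unique(cluster)
    if len(levels) < 2:
        logger.info("single study: fitting plain logistic model")
        return _fixed_fit(X, y, None, "fixed-study")
    cluster_idx = [np.where(cluster == lev)[0] for lev in levels]
    start_model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = start_model.fit(maxiter=100)
    x0 = np.concatenate([start.params, [np.log(0.3)]])
    res = optimize.minimize(
        _mixed_nll, x0, args=(X, y, cluster_idx), method="BFGS",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    sigma = float(np.exp(res.x[-1]))
    if sigma < 1e-3:
        logger.info("random-intercept variance at zero boundary; using fixed study indicators")
        return _fixed_fit(X, y, cluster, "fixed-study")
    H = _numeric_hessian(lambda v: _mixed_nll(v, X, y, cluster_idx), res.x)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:-1], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    return res.x[:-1], se, sigma, "random-intercept"


def _fixed_fit(X, y, cluster, model_type):
    Xf = X
    if cluster is not None:
        levels = pd.unique(cluster)
        dummies = np.column_stack([(cluster == lev).astype(float) for lev in levels[1:]])
        Xf = np.column_stack([X, dummies])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, Xf, family=sm.families.Binomial()).fit(maxiter=200)
    p = X.shape[1]
    return fit.params[:p], fit.bse[:p], 0.0, model_type


# ---------------------------------------------------------------------------
# public operations


def restrict_to_window(annotation: pd.DataFrame, window_years: float) -> pd.DataFrame:
    """Keep cases diagnosed within ``window_years`` of sampling (inclusive)
    and every control."""
    if window_years <= 0:
        raise ValueError("window_years must be > 0")
    ann = annotation
    is_case = ann["case_status"] == "case"
    ttd = pd.to_numeric(ann["time_to_dx_years"], errors="coerce")
    keep = ~is_case | (ttd <= window_years)
    out = ann[keep].reset_index(drop=True)
    if (out["case_status"] == "case").sum() == 0:
        warnings.warn("no cases remain after window restriction", stacklevel=2)
    return out


COMPARISONS = {
    "all_LC": lambda ann: np.ones(len(ann), dtype=bool),
    "NSCLC": lambda ann: (ann["case_status"] != "case")
    | ann["histology"].isin(["AD", "SQ", "OtherNSCLC"]),
    "late_stage": lambda ann: (ann["case_status"] != "case") | (ann["stage"] == "late"),
}


def standardize_by_study(values: np.ndarray, study: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for lev in pd.unique(study):
        m = study == lev
        v = values[m]
        sd = v.std(ddof=1) if m.sum() > 1 else 1.0
        out[m] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def logistic_case_control(
    gene_expr,
    annotation: pd.DataFrame,
    comparison: str = "all_LC",
    window_years: float | None = None,
    gene: str = "gene",
    standardize: bool = True,
    adjust: bool = True,
) -> ORResult:
    """Case-control log-odds model for one gene in the pooled prospective data.

    Adjusts for scaled age, sex and the seven-category smoking variable and
    includes study as a random intercept.  ``window_years`` restricts cases
    to those diagnosed within the window while keeping all controls.
    """
    ann = annotation.reset_index(drop=True).copy()
    ann["_expr"] = np.asarray(gene_expr, dtype=float)
    if window_years is not None:
        ann = restrict_to_window(ann, window_years)
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    ann = ann[COMPARISONS[comparison](ann)].reset_index(drop=True)
    y = (ann["case_status"] == "case").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present after restriction")
    study = ann["study"].to_numpy()
    x = ann["_expr"].to_numpy(dtype=float)
    if standardize:
        x = standardize_by_study(x, study)
    cols = {"intercept": np.ones(len(ann)), "gene": x}
    if adjust:
        if ann["age_years"].nunique() > 1:
            cols["age_scaled"] = scale_covariate(ann["age_years"].to_numpy(dtype=float))
        if ann["sex"].nunique() > 1:
            cols["sex_M"] = (ann["sex"] == "M").astype(float).to_numpy()
        smoking = ann["smoking7"].astype(str)
        for lev in sorted(smoking.unique()):
            if lev == "1":
                continue
            v = (smoking == lev).astype(float).to_numpy()
            if 0 < v.sum() < len(v):
                cols[f"smoking7_{lev}"] = v
    X = np.column_stack(list(cols.values()))
    beta, se, sigma, model_type = fit_logistic_random_intercept(X, y, study)
    j = list(cols).index("gene")
    b, s = float(beta[j]), float(se[j])
    separation = not np.isfinite(s) or abs(b) > 15
    crit = stats.norm.ppf(0.975)
    return ORResult(
        gene=gene,
        comparison=comparison,
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - crit * s)),
        ci_high=float(np.exp(b + crit * s)),
        p=float(2 * stats.norm.sf(abs(b / s))) if s > 0 else np.nan,
        window_years=window_years,
        model_type=model_type,
        coefficient=b,
        se=s,
        sigma_study=sigma,
        separation=separation,
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )


def direction_concordance_test(signs_a, signs_b) -> tuple[int, int, float]:
    """Exact two-sided binomial test of effect-direction concordance.

    Given per-gene effect signs from two cohorts, counts concordant pairs k
    of n and returns (k, n, p) where p = P(X >= k) + P(X <= n - k) for
    X ~ Binomial(n, 1/2) (symmetric two-sided tail).  Pairs with a zero
    sign are excluded with a warning.
    """
    a = np.sign(np.asarray(signs_a, dtype=float))
    b = np.sign(np.asarray(signs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("sign vectors must have equal length")
    nonzero = (a != 0) & (b != 0)
    if (~nonzero).any():
        warnings.warn(f"{int((~nonzero).sum())} gene(s) with zero sign excluded", stacklevel=2)
    a, b = a[nonzero], b[nonzero]
    n = a.size
    if n < 1:
        raise ValueError("no usable sign pairs")
    k = int((a == b).sum())
    lo, hi = min(k, n - k), max(k, n - k)
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    p = float(pmf[: lo + 1].sum() + pmf[hi:].sum())
    return k, n, min(p, 1.0)


def validation_table(results: list[ORResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "comparison": [r.comparison for r in results],
            "window": [r.window_years if r.window_years is not None else "none" for r in results],
            "OR": [r.odds_ratio for r in results],
            "CI_low": [r.ci_low for r in results],
            "CI_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "model_type": [r.model_type for r in results],
        }
    )
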