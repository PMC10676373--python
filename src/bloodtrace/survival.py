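"""Median-dichotomized, stage-stratified proportional-hazards analysis.

The Cox partial likelihood is maximized by Newton-Raphson with either the
Efron (default) or Breslow correction for tied event times; Kaplan-Meier
summaries come from lifelines.  The survival screen fits one model per
(gene, stage stratum) with the gene entering as a median-split indicator,
and adjusts p-values across the screen by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .preprocess import bh_adjust, scale_covariate


def median_dichotomize(values) -> np.ndarray:
    """Label values <= median as "low", otherwise "high"."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(arr)
    labels = np.where(arr <= med, "low", "high")
    if (labels == "low").all():
        warnings.warn("all values at or below the median; every label is 'low'", stacklevel=2)
    return labels


@dataclass
class SurvivalFit:
    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    names: list
    ties: str
    log_partial_likelihood: float
    converged: bool
    separation: bool
    stratum: str | None = None


def _cox_loglik(beta, t, d, X, ties):
    """Log partial likelihood, gradient and Hessian (negated curvature)."""
    n, p = X.shape
    order = np.argsort(-t, kind="stable")  # decreasing time
    ts, ds, Xs = t[order], d[order], X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = np.einsum("i,ip,iq->ipq", w, Xs, Xs)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # accumulate risk set (all with this time enter before events handled)
        S0 += w[i:j].sum()
        S1 += wx[i:j].sum(axis=0)
        S2 += wxx[i:j].sum(axis=0)
        ev = np.where(ds[i:j] == 1)[0] + i
        m = len(ev)
        if m:
            ll += eta[ev].sum()
            grad += Xs[ev].sum(axis=0)
            if ties == "breslow" or m == 1:
                for _ in range(m):
                    ll -= np.log(S0)
                    grad -= S1 / S0
                    hess -= S2 / S0 - np.outer(S1, S1) / S0 ** 2
            else:  # efron
                D0 = w[ev].sum()
                D1 = wx[ev].sum(axis=0)
                D2 = wxx[ev].sum(axis=0)
                for l in range(m):
                    f = l / m
                    a0 = S0 - f * D0
                    a1 = S1 - f * D1
                    a2 = S2 - f * D2
                    ll -= np.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1, a1) / a0 ** 2
        i = j
    return ll, grad, hess


def cox_ph_fit(time, event, covariates, ties: str = "efron", names=None, max_iter: int = 50, tol: float = 1e-9) -> SurvivalFit:
    """Newton-Raphson Cox proportional-hazards fit with Wald inference."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if d.sum() < 1:
        raise ValueError("need at least one event")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariates are rank-deficient (constant or collinear column)")
    X = X - X.mean(axis=0)  # centering improves conditioning; beta unchanged

    beta = np.zeros(X.shape[1])
    converged = False
    separation = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, t, d, X, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # halve steps that do not improve the likelihood
        factor = 1.0
        for _ in range(20):
            new = beta + factor * step
            ll_new, _, _ = _cox_loglik(new, t, d, X, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.linalg.norm(grad) < tol * max(1.0, abs(ll)):
            converged = True
            break
        if np.abs(beta).max() > 50:
            separation = True
            break
    ll, grad, hess = _cox_loglik(beta, t, d, X, ties)
    if not separation and np.linalg.norm(grad) < 1e-6 * max(1.0, abs(ll)):
        converged = True
    # a monotone partial likelihood plateaus: the gradient vanishes while
    # the coefficient drifts without bound
    if np.abs(beta).max() > 10:
        separation = True
    if separation:
        warnings.warn("monotone partial likelihood: coefficient unbounded (separation)", stacklevel=2)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.inf)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(0.975)
    clip = lambda v: np.exp(np.clip(v, -700.0, 700.0))  # noqa: E731  (inf CI for separated fits)
    return SurvivalFit(
        coefficients=beta,
        se=se,
        hr=clip(beta),
        ci_low=clip(beta - crit * se),
        ci_high=clip(beta + crit * se),
        p=p,
        names=names,
        ties=ties,
        log_partial_likelihood=float(ll),
        converged=converged,
        separation=separation,
    )


def survival_screen(candidates, expr: pd.DataFrame, annotation: pd.DataFrame, ties: str = "efron") -> pd.DataFrame:
    """Per-(gene, stage) Cox screen of median-split candidate expression.

    Models adjust for scaled age, sex and smoking status; p-values are
    BH-adjusted across the whole screen.
    """
    genes = list(candidates.genes) if hasattr(candidates, "genes") else list(candidates)
    ann = annotation.reset_index(drop=True)
    cases = ann[(ann["case_status"] == "case") & ann["survival_time"].notna()].copy()
    rows = []
    for stage in ("early", "middle", "late"):
        sub = cases[cases["stage"] == stage]
        if len(sub) < 5 or sub["event"].astype(float).sum() < 1:
            warnings.warn(f"stage stratum {stage!r} has no usable events; skipped", stacklevel=2)
            continue
        idx = sub["sample_id"].tolist()
        cov_base = pd.DataFrame(index=sub.index)
        if sub["age_years"].nunique() > 1:
            cov_base["age_scaled"] = scale_covariate(sub["age_years"].to_numpy(dtype=float))
        if sub["sex"].nunique() > 1:
            cov_base["sex_M"] = (sub["sex"] == "M").astype(float)
        if sub["smoking_status"].nunique() > 1:
            cov_base["smoking_ever"] = (sub["smoking_status"] == "ever").astype(float)
        for gene in genes:
            if gene not in expr.index:
                continue
            vals = expr.loc[gene, idx].to_numpy(dtype=float)
            labels = median_dichotomize(vals)
            if (labels == "low").all() or (labels == "high").all():
                warnings.warn(f"gene {gene} constant after median split in stage {stage}; skipped", stacklevel=2)
                continue
            cov = cov_base.copy()
            cov.insert(0, "high_expr", (labels == "high").astype(float))
            try:
                fit = cox_ph_fit(
                    sub["survival_time"].to_numpy(dtype=float),
                    sub["event"].to_numpy(dtype=int),
                    cov,
                    ties=ties,
                )
            except ValueError as exc:
                warnings.warn(f"cox fit skipped for {gene}/{stage}: {exc}", stacklevel=2)
                continue
            j = fit.names.index("high_expr")
            rows.append(
                {
                    "gene": gene,
                    "stage": stage,
                    "HR": fit.hr[j],
                    "CI_low": fit.ci_low[j],
                    "CI_high": fit.ci_high[j],
                    "p": fit.p[j],
                    "separation": fit.separation,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["FDR"] = bh_adjust(out["p"].to_numpy())
    return out


def kaplan_meier(time, event, groups) -> pd.DataFrame:
    """Product-limit survival estimates per group (Greenwood variance).

    Returns a long-format table (group, time, survival, lower, upper).
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    frames = []
    for lev in pd.unique(g):
        mask = g == lev
        if mask.sum() == 0:
            raise ValueError(f"group {lev!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], d[mask], label=str(lev))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        frames.append(
            pd.DataFrame(
                {
                    "group": str(lev),
                    "time": sf.index.to_numpy(),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "lower": ci.iloc[:, 0].to_numpy(),
                    "upper": ci.iloc[:, 1].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
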