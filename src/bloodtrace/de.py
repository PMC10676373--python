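"""Precision-weighted moderated linear models for differential expression.

The engine follows the classical count-aware weighted-linear-model recipe:
log2-RPM values are fit gene-wise by (weighted) least squares, a lowess
curve of sqrt(residual sd) against mean log2 count supplies per-observation
precision weights (weight = predicted sqrt-sd to the power -4), and
gene-wise residual variances are shrunk toward a scaled-inverse-chi-square
prior whose parameters (d0, s0^2) are estimated by moment matching on
log-variances.  Moderated t statistics then use df + d0 degrees of freedom.

The eight cohort subcomparisons (case/control, histology and stage
contrasts) are expressed as contrast vectors on one joint additive model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .datatypes import CountMatrix, ExpressionMatrix
from .preprocess import bh_adjust, log2_rpm, scale_covariate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrices


def check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns involved in the dependency by greedy elimination
        dependent = []
        cols = list(design.columns)
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                dependent.append(cols[j])
            else:
                kept.append(j)
        raise ValueError(f"design matrix is rank-deficient; dependent columns: {dependent}")


def _dummies(series: pd.Series, prefix: str, reference) -> pd.DataFrame:
    levels = [l for l in pd.unique(series.dropna()) if l != reference]
    out = {}
    for lev in sorted(map(str, levels)):
        out[f"{prefix}_{lev}"] = (series.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=series.index)


def build_diagnostic_design(annotation: pd.DataFrame) -> pd.DataFrame:
    """Joint additive design for the diagnostic cohort.

    Columns: intercept, case indicator, stage (middle/late vs early) and
    histology (vs AD) dummies nested within cases, smoking ever, scaled age,
    sex, and batch dummies for technical variation.
    """
    ann = annotation.reset_index(drop=True)
    is_case = (ann["case_status"] == "case").astype(float)
    design = pd.DataFrame({"intercept": np.ones(len(ann))})
    design["case"] = is_case
    stage = ann["stage"].where(ann["case_status"] == "case")
    hist = ann["histology"].where(ann["case_status"] == "case")
    for col, s in (("stage", stage), ("hist", hist)):
        ref = "early" if col == "stage" else "AD"
        d = _dummies(s, col, ref)
        # controls carry 0 in nested case-only columns
        d = d.fillna(0.0)
        for c in d.columns:
            if d[c].nunique() > 1:
                design[c] = d[c]
    design["smoking_ever"] = (ann["smoking_status"] == "ever").astype(float)
    design["age_scaled"] = scale_covariate(ann["age_years"].to_numpy(dtype=float))
    design["sex_M"] = (ann["sex"] == "M").astype(float)
    if "batch" in ann and ann["batch"].notna().any() and ann["batch"].nunique() > 1:
        ref = sorted(map(str, ann["batch"].dropna().unique()))[0]
        for c, v in _dummies(ann["batch"], "batch", ref).items():
            design[c] = v
    design.index = ann["sample_id"] if "sample_id" in ann else ann.index
    check_full_rank(design)
    return design


# ---------------------------------------------------------------------------
# precision weights


@dataclass
class VoomFit:
    log_expression: pd.DataFrame          # genes x samples log2 RPM
    weights: np.ndarray                   # genes x samples, > 0
    trend_x: np.ndarray                   # mean log2 count grid (sorted)
    trend_y: np.ndarray                   # sqrt residual sd at grid


def _predict_trend(x_grid: np.ndarray, y_grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    # linear interpolation, clamped at the boundary values
    return np.interp(x, x_grid, y_grid)


def voom_weights(counts: CountMatrix, design: pd.DataFrame, span: float = 0.5) -> VoomFit:
    """Mean-variance precision weights for count data.

    Per-gene linear fits on log2-RPM, lowess of sqrt(residual sd) on mean
    log2 count, and per-observation weights equal to the interpolated
    sqrt-sd at the fitted log2 count, raised to the power -4.
    """
    check_full_rank(design)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    if counts.counts.shape[0] < 10:
        raise ValueError("need at least 10 genes to fit the mean-variance trend")
    expr = log2_rpm(counts)
    y = expr.values.to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)

    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                      # genes x p
    fitted = beta @ X.T                    # genes x n
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / (n - p))

    # mean log2 count per gene; fitted values on the log2-count scale
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    lo = sm_lowess(sy, sx, frac=span, it=0, return_sorted=True)
    trend_x, trend_y = lo[:, 0], np.maximum(lo[:, 1], 1e-6)
    # collapse duplicate x for interpolation
    trend_x, idx = np.unique(trend_x, return_index=True)
    trend_y = trend_y[idx]

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = _predict_trend(trend_x, trend_y, fitted_logcount.ravel()).reshape(fitted.shape)
    w = pred ** -4.0
    return VoomFit(expr.values, w, trend_x, trend_y)


# ---------------------------------------------------------------------------
# gene-wise weighted least squares


@dataclass
class GeneFits:
    design: pd.DataFrame
    coefficients: np.ndarray   # genes x p
    cov_unscaled: np.ndarray   # genes x p x p, (X' W X)^-1
    s2: np.ndarray             # genes
    df_residual: int
    ave_expr: np.ndarray       # mean log2 expression per gene
    gene_ids: pd.Index


def fit_gene_models(expr: pd.DataFrame | ExpressionMatrix, weights, design: pd.DataFrame) -> GeneFits:
    """Weighted least squares per gene; s2 = weighted RSS / (n - p)."""
    if isinstance(expr, ExpressionMatrix):
        expr = expr.values
    y = expr.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            w = np.broadcast_to(w, y.shape).copy()
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    xtwx = np.einsum("gn,np,nq->gpq", w, X, X)
    xtwy = np.einsum("gn,np->gp", w * y, X)
    cov = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", cov, xtwy)
    resid = y - beta @ X.T
    s2 = np.einsum("gn,gn->g", w, resid ** 2) / (n - p)
    return GeneFits(design, beta, cov, s2, n - p, y.mean(axis=1), expr.index)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


@dataclass
class ModerationFit:
    d0: float                  # prior degrees of freedom (may be inf)
    s0_sq: float               # prior variance
    s2_post: np.ndarray        # posterior variances
    df_residual: np.ndarray    # residual df per gene


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on trigamma(y) = x (monotone decreasing)
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return y


def empirical_bayes_moderation(s2, df) -> ModerationFit:
    """Estimate the scaled-inverse-chi-square prior (d0, s0^2) by moment
    matching of log variances, and return posterior variances.

    If the spread of log s2 is no larger than its theoretical sampling
    minimum, the prior degrees of freedom are infinite and every posterior
    variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if (s2 < 0).any():
        raise ValueError("variances must be >= 0")
    if (df_arr < 1).any():
        raise ValueError("residual df must be >= 1")
    s2_safe = np.maximum(s2, 1e-300)
    z = np.log(s2_safe)
    e = z - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        evar = 0.0
    else:
        evar = e.var(ddof=1)
    evar_adj = evar - np.mean(special.polygamma(1, df_arr / 2.0))
    if evar_adj > 0:
        half_d0 = _trigamma_inverse(evar_adj)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
        s2_post = (d0 * s0_sq + df_arr * s2) / (d0 + df_arr)
    else:
        d0 = np.inf
        # with literally zero spread the chi-square sampling-noise
        # correction does not apply: the only consistent fit is s0^2 = s^2
        s0_sq = float(np.exp(z.mean())) if evar < 1e-15 else float(np.exp(emean))
        s2_post = np.full_like(s2, s0_sq)
    return ModerationFit(d0, s0_sq, s2_post, df_arr)


def no_moderation(fits: GeneFits) -> ModerationFit:
    """Ordinary least-squares variant: d0 = 0, posterior variance = s2."""
    df = np.full(fits.s2.shape, float(fits.df_residual))
    return ModerationFit(0.0, float(np.median(np.maximum(fits.s2, 1e-300))), fits.s2.copy(), df)


# ---------------------------------------------------------------------------
# contrasts


def apply_contrast(fits: GeneFits, moderation: ModerationFit, contrast, contrast_id: str = "contrast") -> pd.DataFrame:
    """Moderated t-test of a contrast c'beta for every gene.

    Returns a table with columns gene_id, contrast, logFC, AveExpr, t,
    P.Value, adj.P.Val.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fits.coefficients.shape[1],):
        raise ValueError("contrast length must equal number of coefficients")
    if np.all(c == 0):
        raise ValueError("contrast must not be all zero")
    logfc = fits.coefficients @ c
    var_unscaled = np.einsum("p,gpq,q->g", c, fits.cov_unscaled, c)
    se = np.sqrt(moderation.s2_post * var_unscaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_total = moderation.df_residual + moderation.d0
    if np.isinf(moderation.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "contrast": contrast_id,
            "logFC": logfc,
            "AveExpr": fits.ave_expr,
            "t": t,
            "P.Value": p,
            "adj.P.Val": bh_adjust(p),
        }
    ).set_index("gene_id", drop=False)


SUBCOMPARISONS = [
    "case_vs_falsepos",
    "AD_vs_SQ",
    "AD_vs_OtherNSCLC",
    "SQ_vs_OtherNSCLC",
    "SCLC_vs_NSCLC",
    "late_vs_falsepos",
    "NSCLC_vs_falsepos",
    "early_vs_late",
]

#: the three case-control subcomparisons used for candidate selection
CASE_CONTROL_CONTRASTS = ["case_vs_falsepos", "NSCLC_vs_falsepos", "late_vs_falsepos"]


def _composition(series: pd.Series, levels) -> dict:
    s = series.dropna().astype(str)
    total = len(s)
    if total == 0:
        return {}
    return {lev: (s == lev).sum() / total for lev in levels}


def _case_average_contrast(design_cols, annotation, case_mask) -> np.ndarray:
    """Contrast for (average case) - control under the nested additive coding.

    The case coefficient alone compares the reference cell (early-stage AD)
    to controls; averaging over the observed stage/histology composition of
    the selected cases gives a population-averaged group difference.
    """
    c = np.zeros(len(design_cols))
    c[design_cols.index("case")] = 1.0
    ann = annotation.loc[case_mask]
    for prefix, column in (("stage", "stage"), ("hist", "histology")):
        comp = _composition(ann[column], sorted(ann[column].dropna().astype(str).unique()))
        for lev, frac in comp.items():
            name = f"{prefix}_{lev}"
            if name in design_cols:
                c[design_cols.index(name)] += frac
    return c


def run_subcomparisons(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    span: float = 0.5,
    moderate: bool = True,
) -> dict[str, pd.DataFrame]:
    """Fit the joint adjusted model once and test the eight subcomparisons.

    Contrasts with an empty group are skipped with a warning.  Group
    contrasts that average over stage/histology composition use the
    observed composition of the cases entering the comparison.
    """
    ann = annotation.reset_index(drop=True)
    design = build_diagnostic_design(ann)
    vfit = voom_weights(counts, design, span=span)
    fits = fit_gene_models(vfit.log_expression, vfit.weights, design)
    mod = empirical_bayes_moderation(fits.s2, fits.df_residual) if moderate else no_moderation(fits)

    cols = list(design.columns)
    is_case = ann["case_status"] == "case"
    hist = ann["histology"].astype(str)
    stage = ann["stage"].astype(str)
    results: dict[str, pd.DataFrame] = {}

    def hist_dummy(level):
        name = f"hist_{level}"
        return cols.index(name) if name in cols else None

    def have(mask) -> bool:
        return bool(mask.sum())

    nsclc_levels = ["AD", "SQ", "OtherNSCLC"]

    for cid in SUBCOMPARISONS:
        c = np.zeros(len(cols))
        ok = True
        if cid == "case_vs_falsepos":
            ok = have(is_case) and have(~is_case)
            if ok:
                c = _case_average_contrast(cols, ann, is_case)
        elif cid in ("AD_vs_SQ", "AD_vs_OtherNSCLC", "SQ_vs_OtherNSCLC"):
            a, b = cid.split("_vs_")
            ok = have(is_case & (hist == a)) and have(is_case & (hist == b))
            if ok:
                for lev, sign in ((a, 1.0), (b, -1.0)):
                    j = hist_dummy(lev)
                    if j is not None:
                        c[j] += sign
        elif cid == "SCLC_vs_NSCLC":
            nsclc_mask = is_case & hist.isin(nsclc_levels)
            ok = have(is_case & (hist == "SCLC")) and have(nsclc_mask)
            if ok:
                j = hist_dummy("SCLC")
                if j is not None:
                    c[j] += 1.0
                comp = _composition(ann.loc[nsclc_mask, "histology"], nsclc_levels)
                for lev, frac in comp.items():
                    j = hist_dummy(lev)
                    if j is not None:
                        c[j] -= frac
        elif cid == "late_vs_falsepos":
            mask = is_case & (stage == "late")
            ok = have(mask) and have(~is_case)
            if ok:
                c = _case_average_contrast(cols, ann.assign(stage="late"), mask)
        elif cid == "NSCLC_vs_falsepos":
            mask = is_case & hist.isin(nsclc_levels)
            ok = have(mask) and have(~is_case)
            if ok:
                c = _case_average_contrast(cols, ann, mask)
        elif cid == "early_vs_late":
            ok = have(is_case & (stage == "early")) and have(is_case & (stage == "late"))
            if ok and "stage_late" in cols:
                c[cols.index("stage_late")] = -1.0
        if not ok or np.all(c == 0):
            warnings.warn(f"subcomparison {cid!r} skipped: empty group or no estimable contrast", stacklevel=2)
            logger.warning("subcomparison %s skipped", cid)
            continue
        results[cid] = apply_contrast(fits, mod, c, contrast_id=cid)
    return results


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
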