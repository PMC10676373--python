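"""Logistic discrimination models, ROC curves and the nested model ladder.

AUCs are in-sample (apparent).  The AUC is computed by the rank
(Mann-Whitney) formulation, which equals the trapezoidal area under the
empirical ROC curve and handles ties by assigning half credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class ROCResult:
    name: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int


def logistic_fit(features, labels):
    """IRLS maximum-likelihood logistic regression.

    Returns (coefficients, fitted probabilities, separated flag).  An
    intercept column is prepended.  Complete separation is flagged but
    probabilities are still returned.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("feature matrix is rank-deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    probs = np.asarray(fit.fittedvalues)
    separated = bool(np.abs(fit.params).max() > 15 and np.all((probs > 0.99) == (y == 1)))
    if separated:
        warnings.warn("complete separation detected in logistic fit", stacklevel=2)
    return np.asarray(fit.params), probs, separated


def auc(scores, labels) -> float:
    """Area under the empirical ROC via the Mann-Whitney rank statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores, labels, name: str = "model") -> ROCResult:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    fpr, tpr, thr = roc_curve(y, s)
    return ROCResult(
        name=name,
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc(s, y),
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )


#: the six ladder models shown in the figure plus the near-identical
#: cell-types-only seventh, reported in the table.
LADDER = [
    ("Smoking", ["smoking"]),
    ("Gene", ["gene"]),
    ("Smoking+Gene", ["smoking", "gene"]),
    ("Smoking+Neu", ["smoking", "Neutrophil"]),
    ("Smoking+Neu+CD4T", ["smoking", "Neutrophil", "CD4T"]),
    ("Smoking+Neu+CD4T+NK+Gene", ["smoking", "Neutrophil", "CD4T", "NK", "gene"]),
    ("Smoking+Neu+CD4T+NK", ["smoking", "Neutrophil", "CD4T", "NK"]),
]


def _smoking_features(ann: pd.DataFrame, smoking: str) -> np.ndarray:
    if smoking == "binary":
        return (ann["smoking_status"] == "ever").astype(float).to_numpy()[:, None]
    s7 = ann["smoking7"].astype(str)
    cols = []
    for lev in sorted(s7.unique())[1:]:
        v = (s7 == lev).astype(float).to_numpy()
        if 0 < v.sum() < len(v):
            cols.append(v)
    return np.column_stack(cols) if cols else np.zeros((len(ann), 0))


def model_ladder(
    gene_values,
    annotation: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    smoking: str = "binary",
    gene: str = "gene",
) -> list[ROCResult]:
    """Fit the nested discrimination models on the same samples.

    ``proportions`` must carry Neutrophil/CD4T/NK columns for the cell-type
    rungs; rungs with missing columns are skipped with a warning.
    """
    ann = annotation.reset_index(drop=True)
    y = (ann["case_status"] == "case").astype(int).to_numpy()
    blocks: dict[str, np.ndarray] = {
        "smoking": _smoking_features(ann, smoking),
        "gene": np.asarray(gene_values, dtype=float)[:, None],
    }
    if proportions is not None:
        props = proportions.loc[ann["sample_id"]] if "sample_id" in ann else proportions
        for ct in ("Neutrophil", "CD4T", "NK"):
            if ct in props.columns:
                blocks[ct] = props[ct].to_numpy(dtype=float)[:, None]
    results = []
    for name, members in LADDER:
        missing = [m for m in members if m not in blocks or blocks[m].shape[1] == 0]
        if missing:
            warnings.warn(f"ladder model {name!r} skipped; missing features {missing}", stacklevel=2)
            continue
        X = np.column_stack([blocks[m] for m in members])
        try:
            _, probs, _ = logistic_fit(X, y)
        except ValueError as exc:
            warnings.warn(f"ladder model {name!r} skipped: {exc}", stacklevel=2)
            continue
        results.append(roc_points(probs, y, name=f"{name.replace('Gene', gene)}"))
    return results


def ladder_table(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.name for r in results],
            "AUC": [r.auc for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_controls": [r.n_controls for r in results],
        }
    )
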