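"""Expression-dependent logFC filtering and candidate-gene selection.

RNA-seq count heteroscedasticity inflates |logFC| for lowly expressed
genes.  A loess curve of |logFC| against average log2 expression, fitted on
the pooled significant genes of the case-control comparisons, provides an
expression-dependent cut-off: a candidate must clear the curve, not just a
flat fold-change threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess


@dataclass
class LoessCurve:
    """Tricube-weighted local-linear fit of |logFC| on average expression."""

    x: np.ndarray          # sorted average log2 expression grid
    fitted: np.ndarray     # fitted |logFC| values, floored at 0
    span: float

    def predict(self, x_new) -> np.ndarray:
        # linear interpolation on the fitted grid, clamped outside [min, max]
        return np.interp(np.asarray(x_new, dtype=float), self.x, self.fitted)


def fit_logfc_loess(avg_expr, abs_logfc, span: float = 0.75) -> LoessCurve:
    x = np.asarray(avg_expr, dtype=float)
    y = np.asarray(abs_logfc, dtype=float)
    if x.shape != y.shape:
        raise ValueError("avg_expr and abs_logfc must have the same length")
    if x.size < 10:
        raise ValueError("need at least 10 points to fit the loess curve")
    if (y < 0).any():
        raise ValueError("abs_logfc must be non-negative")
    lo = sm_lowess(y, x, frac=span, it=0, return_sorted=True)
    gx, gy = lo[:, 0], np.maximum(lo[:, 1], 0.0)
    gx, idx = np.unique(gx, return_index=True)
    return LoessCurve(gx, gy[idx], span)


@dataclass
class CandidateSet:
    """Genes passing the three-part candidate criteria.

    ``table`` has one row per (gene, contrast) pass record; ``genes`` is the
    deduplicated selection in order of decreasing margin above the curve.
    """

    genes: list = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.genes)


def pooled_curve_input(
    de_tables: dict[str, pd.DataFrame],
    fdr_thresh: float = 0.05,
    min_points: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """(AveExpr, |logFC|) pool for fitting the expression-dependent curve.

    The curve estimates the expression-dependent background level of
    |logFC|, so it is fit on the genes declared significant in any of the
    case-control comparisons.  When fewer than ``min_points`` significant
    rows exist the background is not estimable from them (the significant
    set is then dominated by true effects, and a curve through them would
    filter true positives); the pool falls back to all tested rows, which
    directly profiles the heteroscedastic null envelope.
    """
    frames = [t for t in de_tables.values() if not t.empty]
    if not frames:
        return np.array([]), np.array([]), False
    pooled = pd.concat(frames, ignore_index=True)
    sig = pooled[pooled["adj.P.Val"] < fdr_thresh]
    used_significant = len(sig) >= min_points
    src = sig if used_significant else pooled
    return src["AveExpr"].to_numpy(), src["logFC"].abs().to_numpy(), used_significant


def candidate_flags(table: pd.DataFrame, curve: LoessCurve, fdr_thresh: float, min_fc: float) -> pd.DataFrame:
    """Evaluate the three criteria on one DE table.

    (i) absolute fold change > ``min_fc`` (natural scale; the default 1.0
    requires any up- or down-regulation, a value of 2 demands a two-fold
    change); (ii) FDR < fdr_thresh; (iii) |logFC| strictly above the
    expression-dependent loess curve at the gene's average expression.
    """
    out = table.copy()
    abs_lfc = out["logFC"].abs().to_numpy()
    curve_val = curve.predict(out["AveExpr"].to_numpy())
    out["pass_fc"] = abs_lfc >= np.log2(max(min_fc, 1.0)) if min_fc > 1.0 else abs_lfc > 0.0
    out["pass_fdr"] = out["adj.P.Val"].to_numpy() < fdr_thresh
    out["pass_curve"] = abs_lfc > curve_val
    out["curve_value"] = curve_val
    out["margin"] = abs_lfc - curve_val
    out["is_candidate"] = out["pass_fc"] & out["pass_fdr"] & out["pass_curve"]
    return out


def select_candidates(
    de_tables: dict[str, pd.DataFrame],
    curve: LoessCurve,
    fdr_thresh: float = 0.05,
    min_fc: float = 1.0,
    max_n: int = 30,
) -> CandidateSet:
    """Union of genes passing all three criteria in any case-control table.

    If more than ``max_n`` genes qualify, the ``max_n`` with the largest
    |logFC|-above-curve margin are kept (ties broken by gene id).
    """
    records = []
    for cid, table in de_tables.items():
        if table.empty:
            continue
        flagged = candidate_flags(table, curve, fdr_thresh, min_fc)
        records.append(flagged[flagged["is_candidate"]])
    if not records:
        return CandidateSet([], pd.DataFrame())
    hits = pd.concat(records, ignore_index=True)
    # deduplicate across contrasts by best margin, deterministic ordering
    best = (
        hits.sort_values(["margin", "gene_id"], ascending=[False, True])
        .drop_duplicates("gene_id", keep="first")
        .reset_index(drop=True)
    )
    kept = best.head(max_n)
    genes = kept["gene_id"].tolist()
    table = hits[hits["gene_id"].isin(genes)].sort_values(["gene_id", "contrast"]).reset_index(drop=True)
    return CandidateSet(genes, table)


def correlation_clusters(expr: pd.DataFrame, candidates, r_thresh: float = 0.8) -> list[list[str]]:
    """Single-linkage components of the candidate correlation graph.

    Edges connect gene pairs with Pearson r >= r_thresh on their expression
    profiles.  Genes with constant expression have undefined correlation and
    are reported as singletons with a warning.
    """
    genes = list(candidates.genes) if isinstance(candidates, CandidateSet) else list(candidates)
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate genes to cluster")
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    constant = sd == 0
    if constant.any():
        for g in np.asarray(genes)[constant]:
            warnings.warn(f"gene {g} has constant expression; reported as singleton", stacklevel=2)
    ok = ~constant
    clusters: list[list[str]] = []
    ok_genes = [g for g, keep in zip(genes, ok) if keep]
    if len(ok_genes) >= 2:
        r = np.corrcoef(sub[ok])
        adj = csr_matrix((r >= r_thresh).astype(int))
        n_comp, labels = connected_components(adj, directed=False)
        for k in range(n_comp):
            clusters.append([ok_genes[i] for i in np.where(labels == k)[0]])
    elif len(ok_genes) == 1:
        clusters.append(ok_genes)
    clusters.extend([[g] for g, c in zip(genes, constant) if c])
    return sorted(clusters, key=lambda c: (-len(c), c[0]))


def write_curve(curve: LoessCurve, path) -> None:
    pd.DataFrame({"ave_expr": curve.x, "fitted_abs_logfc": curve.fitted}).to_csv(path, sep="\t", index=False)


def write_candidates(candidates: CandidateSet, path) -> None:
    candidates.table.to_csv(path, sep="\t", index=False)
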