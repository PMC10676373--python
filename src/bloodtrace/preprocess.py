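"""Expression filtering, log2-RPM transformation, covariate encoding and
multiple-testing adjustment.

These are the small, heavily reused primitives of the pipeline; each is
deterministic and validated aggressively because every downstream module
depends on them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import RNASEQ, CountMatrix, ExpressionMatrix


def filter_expressed_genes(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_frac: float = 0.2,
    annotated_ids=None,
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_frac`` of samples.

    ``annotated_ids``, when given, additionally restricts the result to that
    id list (an annotation whitelist).  Gene order is preserved.
    """
    if min_cpm <= 0:
        raise ValueError("min_cpm must be > 0")
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts.counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm >= min_cpm).mean(axis=1) >= min_frac
    kept = counts.counts.loc[keep]
    if annotated_ids is not None:
        kept = kept.loc[kept.index.isin(set(annotated_ids))]
    if kept.shape[0] == 0:
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(kept)


def log2_rpm(counts: CountMatrix) -> ExpressionMatrix:
    """log2 reads-per-million with the canonical +0.5/+1 offsets.

    value = log2((count + 0.5) / (library_size + 1) * 1e6).
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    vals = np.log2((counts.counts.to_numpy(dtype=float) + 0.5) / (lib + 1.0) * 1e6)
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, modality=RNASEQ)


def encode_smoking(status: str, pack_years=None):
    """Seven-category smoking variable from status and pack-years.

    Categories: (1) never; former smokers by pack-years (2) <=10.0,
    (3) 10.1-20.0, (4) >=20.1; current smokers (5) <=10.0, (6) 10.1-20.0,
    (7) >=20.1.  Ever-smokers with missing pack-years map to "unknown".
    Pack-years are rounded to one decimal before binning, since the bins
    are decimal-gapped.
    """
    if status not in ("never", "former", "current"):
        raise ValueError(f"invalid smoking status {status!r}")
    if status == "never":
        return 1
    if pack_years is None or (isinstance(pack_years, float) and np.isnan(pack_years)):
        return "unknown"
    py = float(pack_years)
    if py < 0:
        raise ValueError("pack_years must be >= 0")
    py = round(py, 1)
    base = 2 if status == "former" else 5
    if py <= 10.0:
        return base
    if py <= 20.0:
        return base + 1
    return base + 2


def scale_covariate(x) -> np.ndarray:
    """Center to mean 0 and scale to unit sample (n-1) standard deviation."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if np.unique(arr).size < 2:
        raise ValueError("cannot scale a constant vector")
    return (arr - arr.mean()) / arr.std(ddof=1)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
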