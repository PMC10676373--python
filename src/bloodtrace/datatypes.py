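"""Core in-memory containers shared across the pipeline.

Expression data live in pandas DataFrames (genes in rows, samples in
columns); the thin wrappers here carry the metadata the analysis needs
(modality, provenance) without hiding the DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNASEQ = "rnaseq"
MICROARRAY = "microarray"
METHYLATION = "methylation"
EXPRESSION = "expression"


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        arr = c.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of real log2 expression values.

    ``modality`` records whether values are log2 reads-per-million from
    RNA-seq or log2 intensities from a microarray platform.
    """

    values: pd.DataFrame
    modality: str = RNASEQ

    def __post_init__(self) -> None:
        if self.modality not in (RNASEQ, MICROARRAY):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


#: Canonical column set for a sample annotation table.  Columns that do not
#: apply to a given cohort (e.g. survival in a prospective study) hold NA.
ANNOTATION_COLUMNS = [
    "sample_id",
    "case_status",      # "case" or "control" (FalsePos in the diagnostic study)
    "stage",            # early / middle / late, cases only
    "histology",        # AD / SQ / OtherNSCLC / SCLC, cases only
    "sex",              # F / M
    "age_years",
    "smoking_status",   # never / ever
    "pack_years",
    "smoking7",         # 1..7 or "unknown"
    "study",
    "time_to_dx_years", # prospective cases only
    "survival_time",
    "event",
    "batch",
]


def empty_annotation(n: int) -> pd.DataFrame:
    return pd.DataFrame({c: [pd.NA] * n for c in ANNOTATION_COLUMNS})


@dataclass
class SimTruth:
    """Planted ground truth for a simulated cohort."""

    de_gene_ids: set = field(default_factory=set)
    true_logfc: dict = field(default_factory=dict)
    trend_gene_ids: set = field(default_factory=set)
    trend_amplitude: float = 0.0
    proportions: pd.DataFrame | None = None
    hazard_indicator: pd.Series | None = None
    log_hazard_coefs: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
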