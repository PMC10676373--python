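"""Plain-text readers/writers for the pipeline's tabular interchange formats.

Matrices are tab-delimited with the gene id in the first column and sample
ids in the header; annotation tables are CSV with the literal token ``NA``
for missing values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return CountMatrix(df.round().astype(int))


def read_expression_matrix(path, modality: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df.astype(float), modality=modality)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=False, na_rep="NA")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
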