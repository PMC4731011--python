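"""Tab-delimited readers and writers.

Expression matrices are stored as TSV with a ``gene_id`` index column and one
column per time point labelled by hour.  Missing values use the sentinel
``NA``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix

NA_SENTINEL = "NA"


def read_expression_tsv(
    path: str | Path, level: str, scale: str = "natural", replicate: int = 1
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL])
    return ExpressionMatrix(values=df, level=level, scale=scale, replicate=replicate)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{c:g}" for c in matrix.time_grid]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=NA_SENTINEL)


def write_table(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    out = df.copy()
    if out.index.name is None:
        out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=NA_SENTINEL)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL])
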