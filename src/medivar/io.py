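"""TSV readers/writers for the pipeline's tabular currencies.

Matrices travel as TSV with the gene id in the first column and sample ids
as the header; floats are serialized with 17 significant digits so a
write -> read round trip is bit-stable.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_genes",
    "write_genes",
]

_FLOAT_FMT = "%.17g"


class MatrixParseError(ValueError):
    pass


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV; duplicate gene or sample ids are rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()[:5]
        raise MatrixParseError(f"duplicate gene id(s): {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()[:5]
        raise MatrixParseError(f"duplicate sample id(s): {dup}")
    if df.isna().any().any():
        raise MatrixParseError("matrix contains missing values")
    df.index.name = "gene"
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise MatrixParseError("duplicate sample id(s) in annotation")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise MatrixParseError("duplicate gene id(s) in annotation")
    for col in ("hkg_candidate", "negative_control"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index_label="gene")
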