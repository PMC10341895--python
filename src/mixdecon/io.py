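"""Readers/writers for the tabular formats the pipeline touches.

All files are plain delimited text with a header row and row labels in the
first column: bulk expression (genes x samples), signature matrices in the
LM22 dialect (genes x cell types, tab-separated, cell-type names in the
header), and proportion matrices (cell types x samples). TSV is canonical;
CSV is accepted via the dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    MixDeconError,
    ProportionMatrix,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixFileDialect",
    "TSV",
    "CSV",
    "read_expression",
    "read_signature",
    "read_proportions",
    "write_expression",
    "write_signature",
    "write_proportions",
    "write_table",
]


@dataclass(frozen=True)
class MatrixFileDialect:
    delimiter: str = "\t"
    has_header: bool = True
    row_label_column: int = 0
    decimal_mark: str = "."

    def __post_init__(self) -> None:
        if self.delimiter not in ("\t", ","):
            raise ValueError("delimiter must be tab or comma")
        if self.row_label_column != 0:
            raise ValueError("row labels must be in the first column")


TSV = MatrixFileDialect(delimiter="\t")
CSV = MatrixFileDialect(delimiter=",")


def _read_frame(
    path: str | Path, dialect: MatrixFileDialect, col_kind: str = "column"
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if dialect.has_header:
        # pandas silently mangles duplicate header labels; check the raw line
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(dialect.delimiter)[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise MixDeconError(f"duplicate {col_kind} names in {path}: {dupes}")
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=0 if dialect.has_header else None,
        index_col=0,
        decimal=dialect.decimal_mark,
        float_precision="round_trip",
    )
    # locate non-numeric cells precisely rather than failing wholesale
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(coerced.isna().to_numpy() & ~df.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise MixDeconError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if coerced.isna().to_numpy().any():
        raise MixDeconError(f"missing values in {path}")
    return coerced.astype(float)


def read_expression(
    path: str | Path,
    dialect: MatrixFileDialect = TSV,
    unlog: bool = False,
) -> ExpressionMatrix:
    """Read a bulk expression table (genes as rows, samples as columns).

    ``unlog=True`` applies ``2**x`` before construction, for inputs stored in
    log2 scale; the mixing model requires linear signal. Duplicate gene rows
    are collapsed by their mean (logged); duplicate sample columns are an
    error; negative raw values are rejected.
    """
    df = _read_frame(path, dialect, col_kind="sample")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path)
        df = df.groupby(level=0, sort=False).mean()
    if unlog:
        df = np.power(2.0, df)
    elif (df.to_numpy() < 0).any():
        raise MixDeconError(
            f"negative values in {path}; pass unlog=True for log2-scale input"
        )
    return ExpressionMatrix(df)


def read_signature(
    path: str | Path,
    dialect: MatrixFileDialect = TSV,
    unlog: bool = False,
) -> SignatureMatrix:
    """Read an LM22-dialect signature table (genes x cell types, named header)."""
    if not dialect.has_header:
        raise MixDeconError("signature files require a header row of cell-type names")
    df = _read_frame(path, dialect, col_kind="cell-type")
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    if unlog:
        df = np.power(2.0, df)
    sig = SignatureMatrix(df)
    logger.info("read signature %s: %d genes x %d cell types", path, *sig.shape)
    return sig


def read_proportions(
    path: str | Path,
    dialect: MatrixFileDialect = TSV,
    mode: str = "strict",
) -> ProportionMatrix:
    """Read a proportion table (cell types as rows, samples as columns)."""
    df = _read_frame(path, dialect, col_kind="sample")
    return ProportionMatrix(df, mode=mode)


def _write_frame(df: pd.DataFrame, path: str | Path, dialect: MatrixFileDialect) -> Path:
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise MixDeconError("refusing to write an empty matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # repr-precision floats so write -> read round-trips exactly
    df.to_csv(path, sep=dialect.delimiter, lineterminator="\n")
    return path


def write_expression(B: ExpressionMatrix, path: str | Path, dialect: MatrixFileDialect = TSV) -> Path:
    return _write_frame(B.data, path, dialect)


def write_signature(S: SignatureMatrix, path: str | Path, dialect: MatrixFileDialect = TSV) -> Path:
    return _write_frame(S.data, path, dialect)


def write_proportions(P: ProportionMatrix, path: str | Path, dialect: MatrixFileDialect = TSV) -> Path:
    return _write_frame(P.data, path, dialect)


def write_table(df: pd.DataFrame, path: str | Path, dialect: MatrixFileDialect = TSV) -> Path:
    """Write a long-format report table (no row labels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=dialect.delimiter, index=False, lineterminator="\n")
    return path
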