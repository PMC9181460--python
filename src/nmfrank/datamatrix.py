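"""Dense labelled data matrix and delimited-text / MatrixMarket loaders."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class DataMatrix:
    """A dense numeric m x n matrix with optional row/column labels.

    Rows are observations (samples) and columns are variables (genes) by
    default; ``rows_are_observations`` records the orientation so that
    estimators that care about it (e.g. the minimum-average-partial test)
    can honour or override it.
    """

    values: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None
    rows_are_observations: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {self.values.shape}")
        if self.row_labels is not None and len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row_labels length does not match number of rows")
        if self.col_labels is not None and len(self.col_labels) != self.values.shape[1]:
            raise ValueError("col_labels length does not match number of columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_nonnegative(self) -> bool:
        return bool(np.all(self.values >= 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rows_are_observations: bool = True) -> "DataMatrix":
        return cls(
            df.to_numpy(dtype=float),
            row_labels=[str(i) for i in df.index],
            col_labels=[str(c) for c in df.columns],
            rows_are_observations=rows_are_observations,
        )


def as_array(X) -> np.ndarray:
    """Coerce a DataMatrix / DataFrame / array-like to a float ndarray."""
    if isinstance(X, DataMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def load_matrix(path: str | Path, labels: bool = False) -> DataMatrix:
    """Read a matrix from delimited text (TSV/CSV by extension) or MatrixMarket.

    Parameters
    ----------
    path
        ``.mtx`` files are read with :func:`scipy.io.mmread` and densified;
        anything else is treated as delimited text, tab-separated unless the
        extension is ``.csv``.
    labels
        When true, the first row and first column of a delimited file are
        taken as column and row labels.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        M = scipy.io.mmread(path)
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return DataMatrix(np.asarray(M, dtype=float))
    sep = "," if path.suffix == ".csv" else "\t"
    if labels:
        df = pd.read_csv(path, sep=sep, index_col=0)
        return DataMatrix.from_frame(df)
    df = pd.read_csv(path, sep=sep, header=None)
    return DataMatrix(df.to_numpy(dtype=float))


def save_matrix(X, path: str | Path, labels: bool = False) -> None:
    """Write a matrix as TSV/CSV (by extension), optionally with labels."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    if isinstance(X, DataMatrix) and labels:
        X.to_frame().to_csv(path, sep=sep)
    else:
        np.savetxt(path, as_array(X), delimiter=sep, fmt="%.10g")
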