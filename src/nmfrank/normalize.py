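"""Normalization schemes and non-negativity enforcement.

Eight preprocessing schemes commonly applied to expression matrices before
factorization.  Several produce negative entries; NMF input is restored with
:func:`enforce_nonnegative`, which subtracts the global minimum (a rank-one
perturbation) rather than folding or per-axis shifts.
"""

from __future__ import annotations

import numpy as np

from .datamatrix import as_array

NORMALIZATION_METHODS = (
    "none",
    "scale_cols_then_norm_rows",
    "std_rows",
    "std_cols",
    "std_global",
    "center_rows",
    "center_cols",
    "center_rows_then_cols",
)


def _check_variance(sd: np.ndarray, axis_name: str) -> None:
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance {axis_name} at index {bad.tolist()}; cannot standardize")


def apply_normalization(
    X,
    method: str,
    col_scale: str = "max",
    row_norm: str = "l2",
) -> np.ndarray:
    """Apply one of the eight normalization schemes.

    ``scale_cols_then_norm_rows`` first divides each column by its maximum
    (or standard deviation, with ``col_scale="sd"``) and then divides each
    row by its Euclidean norm (or L1 norm, with ``row_norm="l1"``); the
    sub-steps are exposed because the composite convention varies between
    tools.  The ``std_*`` schemes subtract the mean and divide by the
    standard deviation along rows / columns / all entries; the ``center_*``
    schemes only subtract means.
    """
    A = as_array(X).copy()
    if method == "none":
        return A
    if method == "scale_cols_then_norm_rows":
        if col_scale == "max":
            scale = np.abs(A).max(axis=0)
        elif col_scale == "sd":
            scale = A.std(axis=0)
        else:
            raise ValueError(f"unknown col_scale {col_scale!r}")
        if np.any(scale == 0):
            raise ValueError(
                f"zero-scale column at index {np.flatnonzero(scale == 0).tolist()}"
            )
        A = A / scale
        if row_norm == "l2":
            norms = np.linalg.norm(A, axis=1)
        elif row_norm == "l1":
            norms = np.abs(A).sum(axis=1)
        else:
            raise ValueError(f"unknown row_norm {row_norm!r}")
        if np.any(norms == 0):
            raise ValueError(f"zero-norm row at index {np.flatnonzero(norms == 0).tolist()}")
        return A / norms[:, None]
    if method == "std_rows":
        sd = A.std(axis=1)
        _check_variance(sd, "row")
        return (A - A.mean(axis=1, keepdims=True)) / sd[:, None]
    if method == "std_cols":
        sd = A.std(axis=0)
        _check_variance(sd, "column")
        return (A - A.mean(axis=0, keepdims=True)) / sd[None, :]
    if method == "std_global":
        sd = A.std()
        if sd == 0:
            raise ValueError("zero global variance; cannot standardize")
        return (A - A.mean()) / sd
    if method == "center_rows":
        return A - A.mean(axis=1, keepdims=True)
    if method == "center_cols":
        return A - A.mean(axis=0, keepdims=True)
    if method == "center_rows_then_cols":
        A = A - A.mean(axis=1, keepdims=True)
        return A - A.mean(axis=0, keepdims=True)
    raise ValueError(f"unknown normalization method {method!r}")


def enforce_nonnegative(X) -> np.ndarray:
    """Subtract the global minimum when it is negative; otherwise no-op."""
    A = as_array(X)
    lo = A.min()
    if lo < 0:
        return A - lo
    return A
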