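"""Rank selection from reconstruction-error information criteria.

A *fit family* is one NMF fit per candidate rank k (same seed and solver for
every k, no best-of-restarts selection).  With ``X_hat(k) = W(k) @ H(k)``,
``R(k) = ||X - X_hat(k)||_F^2`` the squared Frobenius residual and
``c = min(m, n)``, the criteria are

    BIC1(k) = log R(k) + k * (m+n)/(mn) * log(mn/(m+n))
    BIC2(k) = log R(k) + k * (m+n)/(mn) * log(c^2)
    BIC3(k) = log R(k) + (k/c^2)     * log(c^2)
    RRSSQ(k) = sqrt( R(k) / sum_ij X_ij^2 )

All four share the residual term and differ only in the (linear-in-k)
penalty, except RRSSQ which has none.  A rank is read off a curve either at
its largest second difference (the default "elbow" rule: the point where a
steep drop is followed by a flat tail) or at its argmin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datamatrix import as_array
from .nmf import NMF, FitConfig, NMFResults, frobenius_loss
from .selection import RankEstimate

_EPS = 1e-300


@dataclass
class FitFamily:
    """One factorization per candidate rank, sharing solver and seed."""

    fits: Mapping[int, NMFResults]
    k_range: np.ndarray
    config: FitConfig

    def __post_init__(self) -> None:
        self.k_range = np.asarray(self.k_range, dtype=int)
        missing = [int(k) for k in self.k_range if int(k) not in self.fits]
        if missing:
            raise ValueError(f"family is missing fits for k = {missing}")

    def residuals(self, X) -> np.ndarray:
        X = as_array(X)
        return np.array(
            [frobenius_loss(X, self.fits[int(k)].W, self.fits[int(k)].H) for k in self.k_range]
        )


def fit_family(X, k_range: Sequence[int], config: FitConfig | None = None) -> FitFamily:
    """Fit one NMF per candidate rank with a shared seed and solver."""
    if config is None:
        config = FitConfig()
    X = as_array(X)
    ks = sorted(int(k) for k in k_range)
    fits = {k: NMF(X, k).fit(config) for k in ks}
    return FitFamily(fits=fits, k_range=np.asarray(ks), config=config)


def bic_curves(X, family: FitFamily) -> dict[str, np.ndarray]:
    """The three BIC-style criterion curves over the family's candidate ranks."""
    X = as_array(X)
    m, n = X.shape
    c = min(m, n)
    ks = family.k_range.astype(float)
    log_resid = np.log(np.maximum(family.residuals(X), _EPS))
    coef = (m + n) / (m * n)
    return {
        "bic1": log_resid + ks * coef * np.log(m * n / (m + n)),
        "bic2": log_resid + ks * coef * np.log(c**2),
        "bic3": log_resid + (ks / c**2) * np.log(c**2),
    }


def rrssq_curve(X, family: FitFamily) -> np.ndarray:
    """Relative root of the sum of squared differences for each candidate rank."""
    X = as_array(X)
    total = float(np.sum(X * X))
    if total == 0:
        raise ZeroDivisionError("X is identically zero; RRSSQ is undefined")
    return np.sqrt(family.residuals(X) / total)


def select_from_curve(
    curve: Sequence[float],
    k_range: Sequence[int] | None = None,
    rule: str = "elbow_second_difference",
) -> int | None:
    """Read a rank off a criterion curve.

    The default elbow rule returns the candidate with the largest positive
    second difference -- a steep drop followed by flattening.  When every
    second difference is <= 0 (e.g. a straight line) there is no interior
    elbow and ``None`` is returned, reproducing boundary failures at the
    ends of the candidate range.  ``rule="argmin"`` returns the curve's
    minimiser instead.
    """
    y = np.asarray(curve, dtype=float)
    if y.size < 3:
        raise ValueError("curve must have at least 3 points")
    ks = np.arange(1, y.size + 1) if k_range is None else np.asarray(k_range, dtype=int)
    if ks.size != y.size:
        raise ValueError("curve and k_range lengths differ")
    if rule == "argmin":
        return int(ks[np.argmin(y)])
    if rule != "elbow_second_difference":
        raise ValueError(f"unknown rule {rule!r}")
    second = y[2:] - 2.0 * y[1:-1] + y[:-2]  # indexed by interior points
    best = int(np.argmax(second))
    if second[best] <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return None
    return int(ks[best + 1])


def select_ic(
    X,
    family: FitFamily,
    criterion: str,
    rule: str = "elbow_second_difference",
) -> RankEstimate:
    """Rank estimate from one of BIC1/BIC2/BIC3/RRSSQ over a fit family."""
    if criterion == "rrssq":
        curve = rrssq_curve(X, family)
    else:
        curves = bic_curves(X, family)
        if criterion not in curves:
            raise ValueError(f"unknown criterion {criterion!r}")
        curve = curves[criterion]
    k_hat = select_from_curve(curve, family.k_range, rule=rule)
    return RankEstimate(
        method=criterion,
        k_hat=k_hat,
        curve=curve,
        k_range=family.k_range,
        diagnostics={"rule": rule},
    )
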