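"""Rank selection from the data matrix alone, via PCA.

Three deterministic estimators of the number of components:

* :func:`velicer_map` -- Velicer's minimum average partial (MAP) test.  A
  full PCA of the variable correlation matrix is performed; for each p the
  first p components are partialled out and the average squared off-diagonal
  partial correlation recorded; the p minimising that average is the
  estimate (p = 0, the raw correlations, is a legal answer).

* :func:`minka_laplace` -- the Laplace approximation to the Bayesian model
  evidence of a probabilistic-PCA model with k retained components; the
  estimate is the k with the largest approximate log-evidence.

* :func:`minka_bic` -- the cruder BIC-style simplification of the same
  evidence, dropping the Laplace curvature and prior terms.

The evidence approximations are evaluated from the eigenvalues of the
(column-centred) sample covariance; with fewer observations than variables
only the leading eigenvalues are nonzero and the candidate range is capped
accordingly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .datamatrix import DataMatrix, as_array
from .selection import RankEstimate

_LOG_EPS = 1e-300


def _orient(X, orient: str) -> np.ndarray:
    A = as_array(X)
    if orient == "columns_are_observations":
        return A.T
    if orient == "rows_are_observations":
        return A
    if orient == "auto":
        if isinstance(X, DataMatrix) and not X.rows_are_observations:
            return A.T
        return A
    raise ValueError(f"unknown orientation {orient!r}")


def velicer_map(X, orient: str = "auto", k_max: int | None = None) -> RankEstimate:
    """Velicer's minimum average partial (MAP) test.

    Parameters
    ----------
    X
        Data matrix; after orientation, rows are observations and columns
        are the variables whose correlation matrix is analysed.  Note the
        correlation matrix is n_variables x n_variables, so wide matrices
        cost O(n_variables^2) memory and time.
    orient
        "rows_are_observations" (default for plain arrays), or
        "columns_are_observations" to transpose first.
    k_max
        Cap on the number of components partialled out; defaults to the
        number of positive correlation eigenvalues minus one.

    Returns
    -------
    RankEstimate with ``k_hat`` the argmin of the average squared partial
    correlation and ``curve`` the averages for p = 0, 1, 2, ...
    """
    A = _orient(X, orient)
    N, p = A.shape
    if N < 3 or p < 3:
        raise ValueError(f"need at least 3 observations and 3 variables; got {A.shape}")
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance variable(s) at column index {bad.tolist()}")
    Z = (A - A.mean(axis=0)) / sd
    R = (Z.T @ Z) / (N - 1)
    np.fill_diagonal(R, 1.0)
    # correlation eigenstructure via the economy SVD of the standardised data
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (N - 1)
    pos = eig > max(eig[0], 1.0) * 1e-12
    eig, V = eig[pos], Vt[pos].T
    n_comp = eig.size
    # partialling out every positive component always leaves a zero matrix,
    # so the last step is only admitted when the spectrum is exactly
    # rank-deficient (there the zero residual is informative, not trivial)
    deficient = n_comp < min(N - 1, p)
    limit = n_comp if deficient else n_comp - 1
    if k_max is not None:
        limit = min(limit, k_max)

    off_n = p * (p - 1)
    avg_sq = [float((np.sum(R * R) - p) / off_n)]
    C = R.copy()
    for j in range(limit):
        a = V[:, j] * np.sqrt(eig[j])  # loading vector of component j
        C -= np.outer(a, a)
        d = np.diag(C).copy()
        if np.any(d <= 1e-12):
            if np.abs(C).max() <= 1e-10:
                # residual variance exhausted: an exact fit, nothing left
                # to correlate, so the average partial correlation is 0
                avg_sq.append(0.0)
            break
        w = 1.0 / d
        # average squared off-diagonal partial correlation without forming
        # the full scaled matrix: sum_ij C_ij^2 w_i w_j minus the diagonal
        total = float(w @ (C * C) @ w)
        avg_sq.append((total - p) / off_n)
    curve = np.asarray(avg_sq)
    k_hat = int(np.argmin(curve))
    return RankEstimate(
        method="velicer_map",
        k_hat=k_hat,
        curve=curve,
        k_range=np.arange(curve.size),
        diagnostics={"n_observations": N, "n_variables": p},
    )


def _covariance_eigenvalues(X) -> tuple[np.ndarray, int, int]:
    A = as_array(X)
    N, d = A.shape
    if N < 2:
        raise ValueError("need at least 2 observations")
    A0 = A - A.mean(axis=0)
    s = np.linalg.svd(A0, compute_uv=False)
    eig = s**2 / N  # maximum-likelihood covariance eigenvalues
    if eig[0] <= 0:
        raise ValueError("degenerate covariance: all observations identical")
    return eig, N, d


def _ppca_terms(eig: np.ndarray, n: int, d: int, k_max: int | None):
    keep = eig > eig[0] * 1e-12
    e = eig[keep]
    # an exactly rank-deficient spectrum (fewer nonzero eigenvalues than the
    # centred data could support) admits its own rank as a candidate: the
    # residual variance there is zero and the evidence is overwhelming
    deficient = e.size < min(n - 1, d)
    limit = min(e.size if deficient else e.size - 1, d - 1)
    if k_max is not None:
        limit = min(limit, k_max)
    if limit < 1:
        raise ValueError("degenerate spectrum: fewer than 2 distinct components")
    return e, limit


def laplace_evidence(eig: np.ndarray, n: int, d: int, k: int) -> float:
    """Laplace-approximate log-evidence of probabilistic PCA with k components.

    ``eig`` holds the nonzero ML covariance eigenvalues (descending), ``n``
    the number of observations and ``d`` the ambient number of variables;
    eigenvalues beyond ``len(eig)`` are treated as exactly zero.
    """
    e = np.asarray(eig, dtype=float)
    v = float(np.sum(e[k:]) / (d - k))
    v = max(v, _LOG_EPS)
    loglik = -0.5 * n * float(np.sum(np.log(e[:k]))) - 0.5 * n * (d - k) * np.log(v)
    # log prior mass of the Stiefel manifold of k principal directions
    i = np.arange(1, k + 1)
    log_pu = -k * np.log(2.0) + float(
        np.sum(gammaln((d - i + 1) / 2.0) - (d - i + 1) / 2.0 * np.log(np.pi))
    )
    m_params = d * k - k * (k + 1) / 2.0
    # log-determinant of the curvature (Hessian) block A_z
    e_hat = np.concatenate([e[:k], np.full(e.size - k, v)])
    log_det = 0.0
    n_hidden = d - e.size  # eigenvalues identically zero, lumped
    for i in range(k):
        j = np.arange(i + 1, e.size)
        # floor the pairwise gaps: exactly tied eigenvalues would otherwise
        # send the log-determinant to -inf
        log_det += float(
            np.sum(
                np.log(np.maximum(1.0 / e_hat[j] - 1.0 / e_hat[i], _LOG_EPS))
                + np.log(np.maximum(e[i] - e[j], _LOG_EPS))
                + np.log(n)
            )
        )
        if n_hidden > 0:
            log_det += n_hidden * (
                np.log(np.maximum(1.0 / v - 1.0 / e_hat[i], _LOG_EPS))
                + np.log(e[i])
                + np.log(n)
            )
    return (
        log_pu
        + loglik
        + (m_params + k) / 2.0 * np.log(2.0 * np.pi)
        - 0.5 * log_det
        - k / 2.0 * np.log(n)
    )


def bic_evidence(eig: np.ndarray, n: int, d: int, k: int) -> float:
    """BIC-style approximate log-evidence of probabilistic PCA with k components.

    Unlike the Laplace form, this approximation has no curvature term to
    temper the noise-variance estimate, so in the undersampled regime
    (fewer observations than variables) it is evaluated with the effective
    dimensionality: callers should pass ``d = len(eig)``.  With n >= d the
    two conventions coincide.
    """
    e = np.asarray(eig, dtype=float)
    loglik = -0.5 * n * float(np.sum(np.log(e[:k])))
    if d > k:  # noise term absent when the model saturates the spectrum
        v = max(float(np.sum(e[k:]) / (d - k)), _LOG_EPS)
        loglik -= 0.5 * n * (d - k) * np.log(v)
    m_params = d * k - k * (k + 1) / 2.0
    return loglik - (m_params + k) / 2.0 * np.log(n)


def _minka(X, evidence, name: str, k_max: int | None, effective_d: bool) -> RankEstimate:
    eig, n, d = _covariance_eigenvalues(X)
    e, limit = _ppca_terms(eig, n, d, k_max)
    if effective_d:
        # dimensionality actually resolvable from n observations
        d = min(n - 1, d)
    ks = np.arange(1, limit + 1)
    curve = np.array([evidence(e, n, d, int(k)) for k in ks])
    k_hat = int(ks[np.argmax(curve)])
    return RankEstimate(
        method=name,
        k_hat=k_hat,
        curve=curve,
        k_range=ks,
        diagnostics={"n_observations": n, "n_variables": d, "n_eigenvalues": e.size},
    )


def minka_laplace(X, k_max: int | None = None) -> RankEstimate:
    """Rank selection by the Laplace approximation to the PCA model evidence."""
    return _minka(X, laplace_evidence, "minka_laplace", k_max, effective_d=False)


def minka_bic(X, k_max: int | None = None) -> RankEstimate:
    """Rank selection by the BIC approximation to the PCA model evidence."""
    return _minka(X, bic_evidence, "minka_bic", k_max, effective_d=True)
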