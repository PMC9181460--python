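"""Non-negative matrix factorization solvers.

Two solvers are provided, both minimising over non-negative W (m x k) and
H (k x n) for a non-negative data matrix X (m x n):

* ``lee_seung_kl`` -- the classical multiplicative-update recurrence for the
  generalized Kullback-Leibler divergence
  ``D(X || WH) = sum_ij [ X_ij log(X_ij / (WH)_ij) - X_ij + (WH)_ij ]``.
  Each sweep updates H, then W, then rescales each column of W to unit sum;
  the updates keep every entry non-negative and never increase the
  divergence.  Iteration stops when the per-sweep change in the divergence
  drops below ``tol``.

* ``projected_gradient_euclidean`` -- alternating non-negative least squares
  for the squared Frobenius loss ``||X - WH||_F^2``, each subproblem solved
  by gradient steps projected onto the non-negative orthant with an
  Armijo-type backtracking step search.  Iteration stops when the relative
  loss change per sweep drops below ``tol``.

W and H are initialised with seeded Uniform(0, 1) entries rescaled so that
the mean of W @ H matches the mean of X; different seeds may (and do) reach
different local minima, so only objective monotonicity -- not the factors
themselves -- is reproducible across seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamatrix import as_array

# Floor applied to denominators and log arguments; 0*log(0) is taken as 0.
EPS = 1e-12


def _check_shapes(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    if W.shape[0] != X.shape[0] or H.shape[1] != X.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: X is {X.shape}, W is {W.shape}, H is {H.shape}"
        )


def kl_divergence(X, W, H) -> float:
    """Generalized Kullback-Leibler divergence D(X || W @ H).

    Returns ``sum_ij [ X_ij log(X_ij/(WH)_ij) - X_ij + (WH)_ij ]``; zero
    entries of X contribute only their ``(WH)_ij`` term (0*log 0 = 0).
    """
    X, W, H = as_array(X), as_array(W), as_array(H)
    _check_shapes(X, W, H)
    WH = np.maximum(W @ H, EPS)
    Xp = np.maximum(X, EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(Xp / WH) - X, 0.0)
    return float(np.sum(term) + np.sum(WH))


def frobenius_loss(X, W, H) -> float:
    """Squared Frobenius norm of the residual, ``||X - W @ H||_F^2``."""
    X, W, H = as_array(X), as_array(W), as_array(H)
    _check_shapes(X, W, H)
    R = X - W @ H
    return float(np.sum(R * R))


def lee_seung_step(X, W, H) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative-update sweep for the KL objective.

    Updates H, then W, then divides each column of W by its column sum.
    Assumes W's columns currently sum to one (as maintained by the solver),
    which folds the usual update denominators into the column scaling.
    """
    X, W, H = as_array(X), as_array(W), as_array(H)
    _check_shapes(X, W, H)
    WH = np.maximum(W @ H, EPS)
    H = H * (W.T @ (X / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
    WH = np.maximum(W @ H, EPS)
    W = W * ((X / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
    W = W / np.maximum(W.sum(axis=0, keepdims=True), EPS)
    return W, H


@dataclass(frozen=True)
class FitConfig:
    """Solver configuration.

    tol is the threshold on the absolute per-iteration change of the KL
    divergence for the multiplicative solver, and on the relative change of
    the Frobenius loss for the projected-gradient solver.
    """

    solver: str = "projected_gradient_euclidean"
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    inner_max_iter: int = 20

    def __post_init__(self) -> None:
        if self.solver not in ("lee_seung_kl", "projected_gradient_euclidean"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class NMFResults:
    """A fitted factorization: the factors plus fit diagnostics."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: str  # "kl" or "frobenius"
    loss_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def summary(self) -> str:
        lines = [
            "NMF fit",
            "-------",
            f"shape:       {self.W.shape[0]} x {self.H.shape[1]}",
            f"rank k:      {self.k}",
            f"objective:   {self.objective}",
            f"iterations:  {self.n_iter}",
            f"converged:   {self.converged}",
            f"final loss:  {self.final_loss:.6g}",
            f"seed:        {self.seed}",
        ]
        return "\n".join(lines)


# Spec-facing alias: a fitted factorization object.
Factorization = NMFResults


class NMF:
    """Non-negative matrix factorization model X ~ W @ H at a fixed rank.

    Parameters
    ----------
    X
        Non-negative data matrix (DataMatrix, DataFrame or ndarray).
    k
        Factorization rank; must satisfy ``1 <= k <= min(m, n) - 1``.
    """

    def __init__(self, X, k: int):
        X = as_array(X)
        if np.any(X < 0):
            raise ValueError(
                "X has negative entries; normalize and enforce non-negativity "
                "(see nmfrank.normalize.enforce_nonnegative) before fitting"
            )
        m, n = X.shape
        if not (1 <= k <= min(m, n) - 1):
            raise ValueError(f"k must satisfy 1 <= k <= min(m, n) - 1; got k={k} for {m} x {n}")
        if (m + n) * k >= m * n:
            warnings.warn(
                f"(m + n) * k = {(m + n) * k} >= m * n = {m * n}: the factorization "
                "has more parameters than data entries",
                stacklevel=2,
            )
        self.X = X
        self.k = k

    def _init_factors(self, seed: int) -> tuple[np.ndarray, np.ndarray]:
        m, n = self.X.shape
        rng = np.random.default_rng(seed)
        W = rng.uniform(size=(m, self.k))
        H = rng.uniform(size=(self.k, n))
        scale = max(self.X.mean(), EPS) / max((W @ H).mean(), EPS)
        s = np.sqrt(scale)
        return W * s, H * s

    def fit(self, config: FitConfig | None = None, **kwargs) -> NMFResults:
        """Fit the factorization; keyword arguments override config fields."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            config = FitConfig(**{**config.__dict__, **kwargs})
        if config.solver == "lee_seung_kl":
            return self._fit_kl(config)
        return self._fit_pg(config)

    def _fit_kl(self, config: FitConfig) -> NMFResults:
        X = self.X
        W, H = self._init_factors(config.seed)
        # maintain the unit-column-sum convention from the start
        scale = W.sum(axis=0, keepdims=True)
        W = W / np.maximum(scale, EPS)
        H = H * scale.T
        trace = [kl_divergence(X, W, H)]
        converged = False
        it = 0
        for it in range(1, config.max_iter + 1):
            W, H = lee_seung_step(X, W, H)
            trace.append(kl_divergence(X, W, H))
            if abs(trace[-2] - trace[-1]) < config.tol:
                converged = True
                break
        return NMFResults(
            W=W, H=H, k=self.k, objective="kl",
            loss_trace=np.asarray(trace), seed=config.seed, n_iter=it,
            converged=converged,
        )

    def _fit_pg(self, config: FitConfig) -> NMFResults:
        X = self.X
        W, H = self._init_factors(config.seed)
        trace = [frobenius_loss(X, W, H)]
        converged = False
        it = 0
        for it in range(1, config.max_iter + 1):
            Wt = _nls_projected_gradient(X.T, H.T, W.T, config.inner_max_iter)
            W = Wt.T
            H = _nls_projected_gradient(X, W, H, config.inner_max_iter)
            trace.append(frobenius_loss(X, W, H))
            prev = max(trace[-2], EPS)
            if (trace[-2] - trace[-1]) / prev < config.tol:
                converged = True
                break
        return NMFResults(
            W=W, H=H, k=self.k, objective="frobenius",
            loss_trace=np.asarray(trace), seed=config.seed, n_iter=it,
            converged=converged,
        )


def _nls_projected_gradient(
    V: np.ndarray, W: np.ndarray, H: np.ndarray, max_inner: int,
    sigma: float = 0.01, beta: float = 0.1,
) -> np.ndarray:
    """Approximately solve min_{H >= 0} ||V - W H||_F^2 by projected gradient.

    Gradient steps with Armijo backtracking on the quadratic model; the step
    size is warm-started across iterations.  The objective never increases.
    """
    WtV = W.T @ V
    WtW = W.T @ W
    alpha = 1.0
    for _ in range(max_inner):
        grad = WtW @ H - WtV
        # projected gradient: components free to move
        pg = grad[(grad < 0) | (H > 0)]
        if pg.size == 0 or np.linalg.norm(pg) < 1e-12:
            break
        decr_alpha = None
        Hp = H
        for _trial in range(20):
            Hn = np.maximum(H - alpha * grad, 0.0)
            d = Hn - H
            gradd = float(np.sum(grad * d))
            dQd = float(np.sum((WtW @ d) * d))
            suff_decr = (1 - sigma) * gradd + 0.5 * dQd <= 0
            if decr_alpha is None:
                decr_alpha = not suff_decr
            if decr_alpha:
                if suff_decr:
                    H = Hn
                    break
                alpha *= beta
            else:
                if not suff_decr or np.array_equal(Hp, Hn):
                    H = Hp
                    break
                alpha /= beta
                Hp = Hn
        else:
            H = Hp
    return H


def fit_nmf(X, k: int, config: FitConfig | None = None, **kwargs) -> NMFResults:
    """Functional wrapper: ``NMF(X, k).fit(config)``."""
    return NMF(X, k).fit(config, **kwargs)
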