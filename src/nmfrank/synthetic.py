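"""Synthetic matrices with a known (planted) number of orthogonal components.

A dataset is built as ``X = |W @ H + E|`` where

* ``W`` (m x k0) has mutually orthogonal non-negative columns, realised as
  disjoint contiguous row-support blocks filled with Uniform(0, 1) draws --
  disjoint supports give exactly zero dot products while keeping every entry
  non-negative, and make the planted components easy to visualise;
* ``H`` (k0 x n) holds Uniform(0, 1) draws with a fixed fraction of entries
  (the *sparsity*) forced to exactly zero, the zero positions sampled without
  replacement;
* ``E`` is i.i.d. Gaussian noise with mean zero and standard deviation equal
  to ``noise_sd_frac`` times the mean absolute entry of the noiseless product
  ``W @ H``; the final absolute value folds any negative entries back to the
  non-negative orthant.

All randomness flows from one seeded generator per dataset, drawn in the
fixed order W, then H values, then the sparsity mask, then the noise, so a
spec (including its seed) pins the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults correspond to the reference simulation design: a 100 x 1000
    matrix, 40% sparsity in H, and noise SD at 5% of the mean magnitude of
    the noiseless product.
    """

    k0: int
    m: int = 100
    n: int = 1000
    sparsity: float = 0.40
    noise_sd_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.k0 < min(self.m, self.n)):
            raise ValueError(f"k0 must satisfy 2 <= k0 < min(m, n); got k0={self.k0}, m={self.m}, n={self.n}")
        if not (0 <= self.sparsity < 1):
            raise ValueError(f"sparsity must lie in [0, 1); got {self.sparsity}")
        if self.noise_sd_frac < 0:
            raise ValueError(f"noise_sd_frac must be >= 0; got {self.noise_sd_frac}")


@dataclass
class SyntheticDataset:
    """A generated matrix together with its planted factors."""

    X: np.ndarray
    W_true: np.ndarray
    H_true: np.ndarray
    spec: SyntheticSpec

    @property
    def k0(self) -> int:
        return self.spec.k0


def make_orthogonal_W(m: int, k0: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Build an m x k0 non-negative matrix with exactly orthogonal columns.

    The m rows are partitioned into k0 contiguous blocks of ``m // k0`` rows
    (remainder rows joining the last block); column ``a`` is Uniform(0, 1) on
    its own block and zero elsewhere.  Disjoint supports make every pairwise
    dot product exactly zero.
    """
    if k0 > m:
        raise ValueError(f"k0={k0} exceeds the number of rows m={m}")
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = np.zeros((m, k0))
    block = m // k0
    for a in range(k0):
        lo = a * block
        hi = (a + 1) * block if a < k0 - 1 else m
        W[lo:hi, a] = rng.uniform(0.0, 1.0, size=hi - lo)
    return W


def make_sparse_H(
    k0: int, n: int, sparsity: float = 0.40, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Build a k0 x n matrix of Uniform(0, 1) draws with a fixed zero fraction.

    Exactly ``round(sparsity * k0 * n)`` entry positions, chosen uniformly
    without replacement, are set to zero, so the realised zero fraction
    matches the requested sparsity up to rounding.
    """
    if not (0 <= sparsity < 1):
        raise ValueError(f"sparsity must lie in [0, 1); got {sparsity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H = rng.uniform(0.0, 1.0, size=(k0, n))
    n_zero = int(round(sparsity * k0 * n))
    if n_zero:
        flat = rng.choice(k0 * n, size=n_zero, replace=False)
        H.ravel()[flat] = 0.0
    return H


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one synthetic dataset from a spec.  Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    W = make_orthogonal_W(spec.m, spec.k0, rng)
    H = make_sparse_H(spec.k0, spec.n, spec.sparsity, rng)
    product = W @ H
    if spec.noise_sd_frac > 0:
        sigma = spec.noise_sd_frac * np.mean(np.abs(product))
        noise = rng.normal(0.0, sigma, size=product.shape)
        X = np.abs(product + noise)
    else:
        X = product.copy()
    return SyntheticDataset(X=X, W_true=W, H_true=H, spec=spec)
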