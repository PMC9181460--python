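"""NMF-native rank selection: volume, consensus clustering, bi-cross-validation.

* :func:`fyv` -- Fogel-Young volume.  For each candidate K the NMF is fit
  at rank K and the K estimated components, unit-normalised, span a
  parallelepiped whose Gram-determinant volume ``sqrt(det(V'V))`` is the
  criterion.  While K does not exceed the true rank each component claims a
  genuinely new direction and the volume stays near 1; the first surplus
  component is nearly collinear with an existing one and the volume
  collapses.  The selected rank is the last point before the first drop
  whose magnitude exceeds a fraction (default 25%) of the average drop
  along the curve.

* :func:`ccc_select` -- Brunet's cophenetic correlation coefficient.  For
  each candidate k the NMF is re-run from many random initialisations; each
  run assigns every sample to its dominant component, and the runs' pairwise
  co-clustering indicators average into a consensus matrix.  The cophenetic
  correlation between ``1 - consensus`` and the ultrametric distances of its
  average-linkage dendrogram measures clustering stability; the selected
  rank is the largest k whose coefficient stays within a factor q (default
  0.999) of the maximum over k.  Following Brunet's implementation the
  consensus runs use the multiplicative KL solver and cluster the columns
  of X by their dominant coefficient in H.

* :func:`bcv` -- Owen-Perry bi-cross-validation.  Rows and columns are
  split into folds; for each held-out row-block x column-block A (with the
  retained blocks B, C, D arranged as ``[[A, B], [C, D]]``) the held-out
  block is predicted as ``B @ pinv(D_k) @ C`` from the rank-k truncated SVD
  of D, and the rank minimising the accumulated squared prediction error is
  selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .datamatrix import as_array
from .nmf import NMF, FitConfig
from .selection import RankEstimate


@dataclass
class ConsensusResult:
    """Consensus matrix over repeated NMF runs at one candidate rank."""

    k: int
    consensus: np.ndarray
    ccc: float | None
    n_runs: int


@dataclass
class CccSelection:
    """Cophenetic-correlation curve and the thresholded selection."""

    k_range: np.ndarray
    ccc_by_k: np.ndarray
    q: float
    c_max: float
    c_thr: float
    k_hat: int
    consensus_results: list[ConsensusResult]


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    # reproducible distinct per-run seeds derived from one base seed
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n_runs)]


def _default_consensus_config(seed: int) -> FitConfig:
    # Brunet-style consensus runs: multiplicative KL updates, capped sweeps
    return FitConfig(solver="lee_seung_kl", max_iter=100, tol=1e-7, seed=seed)


def consensus_matrix(
    X,
    k: int,
    n_runs: int = 20,
    seeds: Sequence[int] | None = None,
    config: FitConfig | None = None,
    cluster_rows: bool = False,
    seed: int = 0,
) -> ConsensusResult:
    """Average co-clustering indicator over ``n_runs`` random restarts.

    Each restart fits an NMF at rank k; item i (a column of X by default,
    following Brunet's convention, or a row when ``cluster_rows``) is
    assigned to the component with the largest coefficient (its column of
    H, resp. row of W), and two items are *connected* when they share a
    dominant component.  The consensus matrix is the mean of the runs'
    connectivity matrices: symmetric, unit diagonal, entries in [0, 1].
    When no ``config`` is given the runs use the multiplicative KL solver
    (Brunet's), seeded from ``seed``.
    """
    if k < 2:
        raise ValueError("consensus clustering requires k >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = as_array(X)
    if config is None:
        config = _default_consensus_config(seed)
    if seeds is None:
        seeds = _run_seeds(config.seed, n_runs)
    elif len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    model = NMF(X, k)
    n_items = X.shape[0] if cluster_rows else X.shape[1]
    counts = np.zeros((n_items, n_items))
    for s in seeds:
        res = model.fit(config, seed=int(s))
        labels = np.argmax(res.W, axis=1) if cluster_rows else np.argmax(res.H, axis=0)
        counts += labels[:, None] == labels[None, :]
    consensus = counts / n_runs
    np.fill_diagonal(consensus, 1.0)
    return ConsensusResult(k=k, consensus=consensus, ccc=None, n_runs=n_runs)


def cophenetic_coefficient(consensus: ConsensusResult | np.ndarray) -> float:
    """Cophenetic correlation of the consensus-derived distance matrix.

    Builds ``D = 1 - consensus``, clusters it with average linkage, and
    returns the Pearson correlation between the original and the cophenetic
    (ultrametric) distances.  A constant distance matrix -- perfectly stable
    clustering -- returns 1.0 by convention.
    """
    C = consensus.consensus if isinstance(consensus, ConsensusResult) else np.asarray(consensus)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.ptp(condensed) < 1e-15:
        return 1.0
    Z = linkage(condensed, method="average")
    c, _ = cophenet(Z, condensed)
    if np.isnan(c):  # constant cophenetic distances (single merge height)
        return 1.0
    return float(c)


def ccc_select(
    X,
    k_range: Sequence[int],
    n_runs: int = 20,
    q: float = 0.999,
    config: FitConfig | None = None,
    cluster_rows: bool = False,
    seed: int = 0,
) -> CccSelection:
    """Select the rank by thresholded cophenetic correlation.

    Steps: compute the cophenetic coefficient CCC(k) for every candidate;
    take ``c_max = max_k CCC(k)``; set the threshold ``c_thr = c_max * q``;
    return the *largest* k with ``CCC(k) >= c_thr``.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range is empty")
    results = []
    for k in ks:
        cr = consensus_matrix(
            X, k, n_runs=n_runs, config=config, cluster_rows=cluster_rows, seed=seed
        )
        cr.ccc = cophenetic_coefficient(cr)
        results.append(cr)
    ccc_by_k = np.array([r.ccc for r in results])
    c_max = float(ccc_by_k.max())
    c_thr = c_max * q
    passing = [k for k, c in zip(ks, ccc_by_k) if c >= c_thr]
    return CccSelection(
        k_range=np.asarray(ks),
        ccc_by_k=ccc_by_k,
        q=q,
        c_max=c_max,
        c_thr=c_thr,
        k_hat=int(max(passing)),
        consensus_results=results,
    )


def gram_volume(vectors: np.ndarray) -> float:
    """Volume of the parallelepiped spanned by unit-normalised columns.

    ``sqrt(det(V'V))`` after dividing each column by its Euclidean norm:
    1 for orthonormal columns, 0 for linearly dependent ones.
    """
    V = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        return 0.0
    U = V / norms
    return float(np.sqrt(max(np.linalg.det(U.T @ U), 0.0)))


def volume_curve(
    X,
    k_range: Sequence[int],
    config: FitConfig | None = None,
    basis: str = "components",
) -> np.ndarray:
    """Fogel-Young volume criterion over candidate ranks.

    For each K in ``k_range`` the NMF is fit at rank K and the volume is the
    Gram determinant of the K unit-normalised component basis vectors (the
    columns of W; ``basis="reconstructions"`` uses the vectorised cumulative
    reconstructions at ranks 1..K instead).  At K = 1 the volume is
    identically 1 whatever the data.
    """
    X = as_array(X)
    if config is None:
        config = FitConfig()
    ks = sorted(int(k) for k in k_range)
    if basis == "components":
        return np.array([gram_volume(NMF(X, K).fit(config).W) for K in ks])
    if basis != "reconstructions":
        raise ValueError(f"unknown basis {basis!r}")
    k_top = ks[-1]
    vecs = np.empty((X.size, k_top))
    for k in range(1, k_top + 1):
        res = NMF(X, k).fit(config)
        vecs[:, k - 1] = res.reconstruction.ravel()
    return np.array([gram_volume(vecs[:, :K]) for K in ks])


def _first_big_drop(
    dets: np.ndarray, ks: np.ndarray, frac: float, min_drop: float = 1e-3
) -> tuple[int | None, float]:
    drops = dets[:-1] - dets[1:]
    # the K=1 volume is identically 1 and carries no information, so a
    # decrease out of it is not evidence; consider drops from K >= 2 only
    start = 1 if ks[0] == 1 else 0
    drops = drops[start:]
    ks = ks[start:]
    # decreases below min_drop (numerical noise between already-collapsed
    # values) are treated as flat: they would otherwise dilute the average
    meaningful = drops[drops > min_drop]
    if meaningful.size == 0:
        return None, 0.0
    avg = float(meaningful.mean())
    hits = np.flatnonzero(drops > max(frac * avg, min_drop))
    if hits.size == 0:
        return None, avg
    return int(ks[hits[0]]), avg


def fyv(
    X,
    k_range: Sequence[int],
    config: FitConfig | None = None,
    drop_threshold_frac: float = 0.25,
    basis: str = "components",
) -> RankEstimate:
    """Fogel-Young volume rank selection.

    The selected rank is the first point on the volume curve followed by a
    decrease larger than ``drop_threshold_frac`` times the average decrease
    along the curve.  If no drop qualifies the largest candidate is
    returned with a warning recorded in the diagnostics.
    """
    ks = np.asarray(sorted(int(k) for k in k_range))
    if ks.size < 3:
        raise ValueError("k_range must contain at least 3 candidates")
    dets = volume_curve(X, ks, config, basis=basis)
    k_hat, avg_drop = _first_big_drop(dets, ks, drop_threshold_frac)
    diagnostics = {
        "drop_threshold_frac": drop_threshold_frac,
        "average_drop": avg_drop,
        "basis": basis,
    }
    if k_hat is None:
        k_hat = int(ks[-1])
        diagnostics["warning"] = "no qualifying drop; returning the largest candidate"
    return RankEstimate(method="fyv", k_hat=k_hat, curve=dets, k_range=ks, diagnostics=diagnostics)


def bcv(
    X,
    k_range: Sequence[int],
    row_folds: int = 2,
    col_folds: int = 2,
    seed: int = 0,
) -> RankEstimate:
    """Owen-Perry bi-cross-validation rank selection.

    Rows and columns are randomly partitioned into ``row_folds`` x
    ``col_folds`` blocks; each block is held out in turn and predicted from
    the retained blocks through the rank-k truncated SVD of the retained
    corner.  The selected rank minimises the total held-out squared error.
    """
    X = as_array(X)
    if row_folds < 2 or col_folds < 2:
        raise ValueError("need at least 2 row folds and 2 column folds")
    ks = np.asarray(sorted(int(k) for k in k_range))
    m, n = X.shape
    rng = np.random.default_rng(seed)
    row_fold = rng.permuted(np.arange(m) % row_folds)
    col_fold = rng.permuted(np.arange(n) % col_folds)
    min_block_m = min(np.sum(row_fold != rf) for rf in range(row_folds))
    min_block_n = min(np.sum(col_fold != cf) for cf in range(col_folds))
    if ks[-1] > min(min_block_m, min_block_n):
        raise ValueError(
            f"largest candidate k={ks[-1]} exceeds the retained block size "
            f"{min(min_block_m, min_block_n)}"
        )
    errors = np.zeros(ks.size)
    for rf in range(row_folds):
        held_r = row_fold == rf
        for cf in range(col_folds):
            held_c = col_fold == cf
            A = X[np.ix_(held_r, held_c)]
            B = X[np.ix_(held_r, ~held_c)]
            C = X[np.ix_(~held_r, held_c)]
            D = X[np.ix_(~held_r, ~held_c)]
            U, s, Vt = np.linalg.svd(D, full_matrices=False)
            BV = B @ Vt.T
            UC = U.T @ C
            pred = np.zeros_like(A)
            prev_k = 0
            for i, k in enumerate(ks):
                for j in range(prev_k, k):
                    if s[j] > s[0] * 1e-12:
                        pred += np.outer(BV[:, j] / s[j], UC[j])
                prev_k = k
                errors[i] += float(np.sum((A - pred) ** 2))
    k_hat = int(ks[np.argmin(errors)])
    return RankEstimate(
        method="bcv",
        k_hat=k_hat,
        curve=errors,
        k_range=ks,
        diagnostics={"row_folds": row_folds, "col_folds": col_folds, "seed": seed},
    )
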