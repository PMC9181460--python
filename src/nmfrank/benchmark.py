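"""Benchmark harness: accuracy of rank estimators on synthetic data, and the
effect of normalization on a user-supplied expression matrix.

The accuracy study generates many synthetic datasets at each true rank k0,
applies every configured estimator once per dataset, and aggregates exact
recovery rates, mean/SD of the estimate, and Lin's concordance correlation
between the estimated and true ranks pooled over the study.  Everything is
a pure function of the study configuration: the dataset seed is
``base_seed + 10000 * k0 + rep`` and estimator-internal seeds derive from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamatrix import as_array
from .nmf import FitConfig
from .selection import ALL_METHODS, IC_METHODS
from .synthetic import SyntheticSpec, generate


@dataclass
class ConcordanceResult:
    """Lin's concordance correlation coefficient with a 95% interval."""

    rho_c: float
    ci_low: float
    ci_high: float
    n: int


def lin_concordance(x, y, ci: str = "fisher", n_boot: int = 2000, seed: int = 0) -> ConcordanceResult:
    """Lin's concordance correlation coefficient between paired measurements.

    ``rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    sample (ddof = 1) moments.  The default 95% CI applies the Fisher
    z-transformation to rho_c (approximate); ``ci="bootstrap"`` resamples
    pairs instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("concordance is undefined for a constant vector")

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        cov = np.cov(a, b, ddof=1)[0, 1]
        return float(2 * cov / (va + vb + (a.mean() - b.mean()) ** 2))

    rho = _rho(x, y)
    if ci == "fisher":
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            a, b = x[idx], y[idx]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            stats.append(_rho(a, b))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    return ConcordanceResult(rho_c=rho, ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass
class SimulationStudy:
    """Configuration (and, after running, the raw records) of an accuracy study."""

    k0_range: Sequence[int]
    n_reps: int
    methods: Sequence[str]
    base_seed: int = 0
    m: int = 100
    n: int = 1000
    sparsity: float = 0.40
    noise_sd_frac: float = 0.05
    n_runs: int = 20  # consensus re-initialisations for "ccc"
    q: float = 0.999
    k_extra: int = 5  # iterative methods search 2..k0+k_extra
    full_k_range: bool = False  # force 2..min(20, min(m,n)-1) instead
    fit_config: FitConfig | None = None
    records: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def dataset_seed(self, k0: int, rep: int) -> int:
        return self.base_seed + 10000 * k0 + rep

    def k_range_for(self, k0: int) -> range:
        upper = min(min(self.m, self.n) - 1, 20 if self.full_k_range else k0 + self.k_extra)
        return range(2, upper + 1)


def apply_estimator(
    X,
    method: str,
    k_range: Sequence[int],
    seed: int = 0,
    n_runs: int = 20,
    q: float = 0.999,
    config: FitConfig | None = None,
) -> int | None:
    """Run one named estimator on one matrix and return its selected rank."""
    from . import rank_ic, rank_nmf, rank_pca

    if method == "velicer_map":
        return rank_pca.velicer_map(X).k_hat
    if method == "minka_laplace":
        return rank_pca.minka_laplace(X).k_hat
    if method == "minka_bic":
        return rank_pca.minka_bic(X).k_hat
    if config is None:
        config = FitConfig(seed=seed)
    else:
        config = FitConfig(**{**config.__dict__, "seed": seed})
    if method in IC_METHODS:
        family = rank_ic.fit_family(X, k_range, config)
        return rank_ic.select_ic(X, family, method).k_hat
    if method == "fyv":
        ks = range(1, max(k_range) + 1)
        return rank_nmf.fyv(X, ks, config).k_hat
    if method == "ccc":
        # consensus runs use their own KL default config (Brunet's scheme)
        return rank_nmf.ccc_select(X, k_range, n_runs=n_runs, q=q, seed=seed).k_hat
    if method == "bcv":
        return rank_nmf.bcv(X, k_range, seed=seed).k_hat
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AccuracySummary:
    """Per-(method, k0) aggregates recomputable from the raw records."""

    records: pd.DataFrame  # columns: method, k0, rep, seed, k_hat, error

    def table(self) -> pd.DataFrame:
        rows = []
        for (method, k0), g in self.records.groupby(["method", "k0"], sort=True):
            ok = g["k_hat"].notna()
            kh = g.loc[ok, "k_hat"].astype(float)
            rows.append(
                {
                    "method": method,
                    "k0": k0,
                    "n": len(g),
                    "n_valid": int(ok.sum()),
                    "accuracy": float((kh == k0).mean()) if ok.any() else np.nan,
                    "over_by_one": float((kh == k0 + 1).mean()) if ok.any() else np.nan,
                    "mean_k_hat": float(kh.mean()) if ok.any() else np.nan,
                    "sd_k_hat": float(kh.std(ddof=1)) if ok.sum() > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def accuracy(self, method: str, k0: int | None = None) -> float:
        r = self.records[self.records["method"] == method]
        if k0 is not None:
            r = r[r["k0"] == k0]
        return float((r["k_hat"] == r["k0"]).mean())

    def summary(self) -> str:
        return self.table().to_string(index=False)


def run_accuracy_study(study: SimulationStudy) -> tuple[AccuracySummary, dict[str, ConcordanceResult]]:
    """Run the synthetic accuracy study described by ``study``.

    Generates ``n_reps`` datasets at every k0, applies each estimator once
    per dataset, and stores one record per (method, dataset).  Estimator
    failures are recorded with a reason instead of aborting the study.
    """
    rows = []
    for k0 in study.k0_range:
        for rep in range(study.n_reps):
            seed = study.dataset_seed(k0, rep)
            ds = generate(
                SyntheticSpec(
                    k0=k0,
                    m=study.m,
                    n=study.n,
                    sparsity=study.sparsity,
                    noise_sd_frac=study.noise_sd_frac,
                    seed=seed,
                )
            )
            k_range = study.k_range_for(k0)
            for method in study.methods:
                try:
                    k_hat = apply_estimator(
                        ds.X,
                        method,
                        k_range,
                        seed=seed,
                        n_runs=study.n_runs,
                        q=study.q,
                        config=study.fit_config,
                    )
                    err = None
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    k_hat, err = None, f"{type(exc).__name__}: {exc}"
                rows.append(
                    {"method": method, "k0": k0, "rep": rep, "seed": seed, "k_hat": k_hat, "error": err}
                )
    records = pd.DataFrame(rows)
    study.records = records
    concordance: dict[str, ConcordanceResult] = {}
    for method in study.methods:
        r = records[(records["method"] == method) & records["k_hat"].notna()]
        if len(r) >= 3 and r["k0"].nunique() > 1:
            concordance[method] = lin_concordance(
                r["k_hat"].to_numpy(float), r["k0"].to_numpy(float)
            )
    return AccuracySummary(records), concordance


def cv_filter(X, n_keep: int) -> np.ndarray:
    """Keep the ``n_keep`` columns with the largest coefficient of variation.

    CV = SD / mean per column (variables in columns); the retained columns
    keep their original order.  Columns with zero mean have no defined CV
    and are excluded with a warning rather than ranked first.
    """
    A = as_array(X)
    if n_keep > A.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds the number of columns {A.shape[1]}")
    means = A.mean(axis=0)
    sds = A.std(axis=0, ddof=1)
    zero = np.abs(means) <= 1e-12 * np.maximum(1.0, sds)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-mean column(s) excluded from CV ranking", stacklevel=2
        )
    cv = np.where(zero, -np.inf, sds / np.where(zero, 1.0, np.abs(means)))
    keep = np.sort(np.argsort(cv, kind="stable")[::-1][:n_keep])
    return A[:, keep]


def run_normalization_study(
    X,
    methods: Sequence[str],
    norms: Sequence[str],
    k_range: Sequence[int] | None = None,
    seed: int = 0,
    n_runs: int = 20,
    q: float = 0.999,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Estimate the rank under every (estimator, normalization) combination.

    Returns a methods x normalizations grid of selected ranks; cells where
    an estimator fails hold NaN (the failure reason is warned).  The matrix
    must already be CV-filtered if desired (see :func:`cv_filter`).
    """
    from .normalize import apply_normalization, enforce_nonnegative

    A = as_array(X)
    m, n = A.shape
    if k_range is None:
        k_range = range(2, min(20, min(m, n) - 1) + 1)
    grid = pd.DataFrame(index=list(methods), columns=list(norms), dtype=float)
    for norm in norms:
        Xn = enforce_nonnegative(apply_normalization(A, norm))
        for method in methods:
            try:
                grid.loc[method, norm] = apply_estimator(
                    Xn, method, k_range, seed=seed, n_runs=n_runs, q=q, config=config
                )
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"{method} on {norm}: {type(exc).__name__}: {exc}", stacklevel=2)
                grid.loc[method, norm] = np.nan
    return grid
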