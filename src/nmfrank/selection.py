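"""Result containers and a one-stop model facade for rank selection.

`RankEstimate` is the common return type of every estimator in the package.
`RankSelection` bundles several estimators behind a statsmodels-flavoured
Model/Results pair::

    model = RankSelection(X, methods=["minka_bic", "velicer_map", "ccc"])
    res = model.fit(seed=0)
    print(res.summary())
    res.k_hat  # {"minka_bic": 5, "velicer_map": 5, "ccc": 5}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datamatrix import as_array

#: Estimators that need no NMF fits and search their natural full range.
PCA_METHODS = ("velicer_map", "minka_laplace", "minka_bic")
#: Estimators built on a family of NMF fits across candidate ranks.
IC_METHODS = ("bic1", "bic2", "bic3", "rrssq")
#: NMF-native estimators.
NMF_METHODS = ("fyv", "ccc", "bcv")
ALL_METHODS = PCA_METHODS + IC_METHODS + NMF_METHODS


@dataclass
class RankEstimate:
    """One estimator's answer: the selected rank plus its criterion curve."""

    method: str
    k_hat: int | None
    curve: np.ndarray | None = None
    k_range: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_range is not None:
            self.k_range = np.asarray(self.k_range)
        if self.curve is not None:
            self.curve = np.asarray(self.curve, dtype=float)
            if self.k_range is not None and self.curve.size != self.k_range.size:
                raise ValueError("curve and k_range lengths differ")
        if (
            self.k_hat is not None
            and self.k_range is not None
            and self.k_hat not in self.k_range
        ):
            raise ValueError(f"k_hat={self.k_hat} is outside the searched range")


class RankSelection:
    """Apply a set of rank estimators to one data matrix.

    Parameters
    ----------
    X
        Non-negative data matrix (rows = observations).
    methods
        Estimator names from :data:`ALL_METHODS`; defaults to all ten.
    k_range
        Candidate ranks for the NMF-based estimators (the PCA-based ones
        always search their natural full range).
    """

    def __init__(self, X, methods: Sequence[str] | None = None, k_range: Sequence[int] | None = None):
        self.X = as_array(X)
        self.methods = tuple(methods) if methods is not None else ALL_METHODS
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        m, n = self.X.shape
        if k_range is None:
            k_range = range(2, min(20, min(m, n) - 1) + 1)
        self.k_range = np.asarray(list(k_range), dtype=int)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RankSelection":
        return cls(df.to_numpy(dtype=float), **kwargs)

    def fit(self, seed: int = 0, n_runs: int = 20, q: float = 0.999, **solver_kwargs) -> "RankSelectionResults":
        from . import rank_ic, rank_nmf, rank_pca
        from .nmf import FitConfig

        estimates: dict[str, RankEstimate] = {}
        config = FitConfig(seed=seed, **solver_kwargs)
        family = None
        for method in self.methods:
            if method == "velicer_map":
                estimates[method] = rank_pca.velicer_map(self.X)
            elif method == "minka_laplace":
                estimates[method] = rank_pca.minka_laplace(self.X)
            elif method == "minka_bic":
                estimates[method] = rank_pca.minka_bic(self.X)
            elif method in IC_METHODS:
                if family is None:
                    family = rank_ic.fit_family(self.X, self.k_range, config)
                estimates[method] = rank_ic.select_ic(self.X, family, method)
            elif method == "fyv":
                estimates[method] = rank_nmf.fyv(self.X, self.k_range, config)
            elif method == "ccc":
                sel = rank_nmf.ccc_select(self.X, self.k_range, n_runs=n_runs, q=q, seed=seed)
                estimates[method] = RankEstimate(
                    method="ccc",
                    k_hat=sel.k_hat,
                    curve=sel.ccc_by_k,
                    k_range=sel.k_range,
                    diagnostics={"c_max": sel.c_max, "c_thr": sel.c_thr, "q": sel.q},
                )
            elif method == "bcv":
                estimates[method] = rank_nmf.bcv(self.X, self.k_range, seed=seed)
        return RankSelectionResults(self, estimates)


class RankSelectionResults:
    """Estimates from every requested method, with a summary table."""

    def __init__(self, model: RankSelection, estimates: dict[str, RankEstimate]):
        self.model = model
        self.estimates = estimates

    @property
    def k_hat(self) -> dict[str, int | None]:
        return {m: e.k_hat for m, e in self.estimates.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, e in self.estimates.items():
            rows.append({"method": m, "k_hat": e.k_hat})
        return pd.DataFrame(rows).set_index("method")

    def summary(self) -> str:
        m, n = self.model.X.shape
        head = [
            "Rank selection",
            "--------------",
            f"data:     {m} x {n}",
            f"k range:  {self.model.k_range.min()}..{self.model.k_range.max()} (NMF-based methods)",
            "",
        ]
        return "\n".join(head) + self.to_frame().to_string()
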