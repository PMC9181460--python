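"""Concordance statistic, CV filtering, and study orchestration."""

import numpy as np
import pandas as pd
import pytest

from nmfrank import SimulationStudy, cv_filter, lin_concordance, run_accuracy_study, run_normalization_study
from nmfrank.benchmark import apply_estimator
from nmfrank.synthetic import SyntheticSpec, generate


class TestLinConcordance:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        r = lin_concordance(x, x)
        assert r.rho_c == pytest.approx(1.0)

    def test_negative_for_opposed_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = lin_concordance(x, -x)
        assert r.rho_c < 0

    def test_closed_form_on_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 1.0
        # direct substitution: var = 5/3, cov = 5/3, mean shift = 1
        expected = 2 * (5 / 3) / ((5 / 3) + (5 / 3) + 1.0)
        r = lin_concordance(x, y)
        assert r.rho_c == pytest.approx(expected, rel=1e-12)
        assert -1 <= r.ci_low <= r.rho_c <= r.ci_high <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            lin_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bootstrap_ci_brackets_estimate(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.3, size=40)
        r = lin_concordance(x, y, ci="bootstrap", n_boot=200, seed=1)
        assert r.ci_low <= r.rho_c <= r.ci_high


class TestCvFilter:
    def test_identity_when_keeping_all(self, rng):
        X = rng.uniform(1, 2, (6, 8))
        np.testing.assert_array_equal(cv_filter(X, 8), X)

    def test_keeps_highest_cv_column(self):
        rng = np.random.default_rng(0)
        lo = 10 + 0.1 * rng.normal(size=50)
        hi = 10 + 9.0 * rng.normal(size=50)
        X = np.column_stack([lo, hi])
        kept = cv_filter(X, 1)
        np.testing.assert_array_equal(kept[:, 0], hi)

    def test_matches_independent_sort_oracle(self, rng):
        X = rng.uniform(0.5, 3.0, (10, 50))
        kept = cv_filter(X, 20)
        cv = X.std(axis=0, ddof=1) / X.mean(axis=0)
        top = np.sort(np.argsort(cv)[::-1][:20])
        np.testing.assert_array_equal(kept, X[:, top])

    def test_zero_mean_columns_excluded_with_warning(self):
        X = np.random.default_rng(1).normal(size=(20, 5))
        X[:, 2] -= X[:, 2].mean()
        with pytest.warns(UserWarning):
            kept = cv_filter(X, 4)
        assert kept.shape == (20, 4)


@pytest.fixture(scope="module")
def tiny_study():
    study = SimulationStudy(
        k0_range=[3, 5], n_reps=3, methods=["minka_bic", "minka_laplace"],
        base_seed=7, n=300,
    )
    return run_accuracy_study(study)


class TestAccuracyStudy:
    def test_records_complete_and_accuracy_computable(self, tiny_study):
        summary, conc = tiny_study
        assert len(summary.records) == 2 * 3 * 2
        table = summary.table()
        assert set(table["method"]) == {"minka_bic", "minka_laplace"}
        assert summary.accuracy("minka_bic") == 1.0

    def test_concordance_present_and_high(self, tiny_study):
        _, conc = tiny_study
        assert conc["minka_bic"].rho_c > 0.99

    def test_rerun_reproduces_records(self, tiny_study):
        summary, _ = tiny_study
        study2 = SimulationStudy(
            k0_range=[3, 5], n_reps=3, methods=["minka_bic", "minka_laplace"],
            base_seed=7, n=300,
        )
        summary2, _ = run_accuracy_study(study2)
        pd.testing.assert_frame_equal(summary.records, summary2.records)

    def test_marginals_recompute_from_records(self, tiny_study):
        summary, _ = tiny_study
        table = summary.table()
        row = table[(table["method"] == "minka_bic") & (table["k0"] == 3)].iloc[0]
        r = summary.records
        sub = r[(r["method"] == "minka_bic") & (r["k0"] == 3)]
        assert row["accuracy"] == pytest.approx((sub["k_hat"] == 3).mean())
        assert row["mean_k_hat"] == pytest.approx(sub["k_hat"].mean())

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            SimulationStudy(k0_range=[3], n_reps=1, methods=["pca"])


class TestNormalizationStudy:
    def test_grid_shape_and_content(self):
        ds = generate(SyntheticSpec(k0=3, m=40, n=60, seed=5))
        grid = run_normalization_study(
            ds.X, methods=["minka_bic", "minka_laplace"], norms=["none", "std_cols"], seed=0
        )
        assert grid.shape == (2, 2)
        assert grid.loc["minka_bic", "none"] == 3
        # normalization is allowed to change the estimate; only exploratory
        assert grid.notna().all().all()


class TestApplyEstimator:
    def test_dispatch_covers_every_method_name(self):
        ds = generate(SyntheticSpec(k0=3, m=40, n=80, seed=9))
        from nmfrank.nmf import FitConfig

        cfg = FitConfig(max_iter=60, tol=1e-5, seed=0)
        for method in ("minka_bic", "bcv"):
            k = apply_estimator(ds.X, method, range(2, 7), seed=1, config=cfg)
            assert isinstance(k, int)
        with pytest.raises(ValueError):
            apply_estimator(ds.X, "unknown", range(2, 7))
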