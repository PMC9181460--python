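"""Volume, consensus-clustering and bi-cross-validation selectors."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from nmfrank import (
    FitConfig,
    SyntheticSpec,
    bcv,
    ccc_select,
    consensus_matrix,
    cophenetic_coefficient,
    fyv,
    generate,
)
from nmfrank.rank_nmf import CccSelection, gram_volume

FAST = FitConfig(max_iter=80, tol=1e-6, seed=0)
FAST_KL = FitConfig(solver="lee_seung_kl", max_iter=80, tol=1e-7, seed=0)


class TestGramVolume:
    def test_orthonormal_columns_give_unit_volume(self):
        assert gram_volume(np.eye(4)[:, :3]) == pytest.approx(1.0)

    def test_collinear_columns_give_zero_volume(self):
        v = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        assert gram_volume(v) == pytest.approx(0.0, abs=1e-12)

    def test_volume_invariant_to_column_order_and_scale(self, rng):
        V = rng.uniform(0.1, 1, (20, 4))
        a = gram_volume(V)
        perm = V[:, [2, 0, 3, 1]] * np.array([3.0, 0.5, 7.0, 1.0])
        assert gram_volume(perm) == pytest.approx(a, rel=1e-10)
        assert 0.0 <= a <= 1.0


class TestFyv:
    def test_recovers_planted_rank(self):
        ds = generate(SyntheticSpec(k0=4, m=60, n=120, seed=3))
        est = fyv(ds.X, range(1, 10), FAST)
        assert est.k_hat == 4
        # the volume collapses right after the true rank
        i = list(est.k_range).index(4)
        assert est.curve[i] > 10 * est.curve[i + 1]

    def test_no_qualifying_drop_returns_largest_with_warning(self, monkeypatch):
        # a monotonically rising volume curve has no drop to detect
        import nmfrank.rank_nmf as rn

        monkeypatch.setattr(rn, "volume_curve", lambda *a, **k: np.array([0.5, 0.6, 0.7, 0.8]))
        est = fyv(np.ones((5, 6)), range(1, 5), FAST)
        assert est.k_hat == 4
        assert "warning" in est.diagnostics

    def test_first_drop_rule_skips_trivial_first_point(self):
        from nmfrank.rank_nmf import _first_big_drop

        # the 1 -> 2 decrease is uninformative; the cliff at 3 -> 4 decides
        dets = np.array([1.0, 0.9, 0.89, 0.01, 0.0])
        k_hat, _ = _first_big_drop(dets, np.arange(1, 6), 0.25)
        assert k_hat == 3

    def test_requires_three_candidates(self, small_dataset):
        with pytest.raises(ValueError):
            fyv(small_dataset.X, [2, 3], FAST)


class TestConsensus:
    def test_matrix_exactly_symmetric_unit_diagonal_in_range(self, small_dataset):
        cr = consensus_matrix(small_dataset.X, 3, n_runs=5, config=FAST_KL)
        C = cr.consensus
        assert np.array_equal(C, C.T)
        assert np.array_equal(np.diag(C), np.ones(len(C)))
        assert C.min() >= 0 and C.max() <= 1

    def test_single_run_gives_binary_entries(self, small_dataset):
        cr = consensus_matrix(small_dataset.X, 3, n_runs=1, config=FAST_KL)
        assert set(np.unique(cr.consensus)) <= {0.0, 1.0}

    def test_stable_clustering_gives_binary_consensus(self, noiseless_dataset):
        cr = consensus_matrix(noiseless_dataset.X, 3, n_runs=6, config=FAST_KL)
        off = cr.consensus[np.triu_indices_from(cr.consensus, 1)]
        assert np.mean((off < 0.01) | (off > 0.99)) > 0.9

    def test_k_below_two_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            consensus_matrix(small_dataset.X, 1, n_runs=2)


class TestCophenetic:
    def test_perfect_two_block_consensus_gives_one(self):
        C = np.zeros((8, 8))
        C[:4, :4] = 1.0
        C[4:, 4:] = 1.0
        assert cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_bounded_for_random_symmetric_consensus(self, rng):
        A = rng.uniform(0, 1, (10, 10))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        assert -1.0 <= cophenetic_coefficient(C) <= 1.0

    def test_constant_distances_return_one_by_convention(self):
        C = np.full((6, 6), 0.4)
        np.fill_diagonal(C, 1.0)
        assert cophenetic_coefficient(C) == 1.0

    def test_matches_manual_pearson_of_cophenetic_distances(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        A = rng.uniform(0, 1, (12, 12))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        D = 1 - C
        np.fill_diagonal(D, 0.0)
        y = squareform(D, checks=False)
        Z = linkage(y, method="average")
        _, coph = cophenet(Z, y)
        r, _ = pearsonr(y, coph)
        assert cophenetic_coefficient(C) == pytest.approx(r, rel=1e-10)


class TestCccSelect:
    def test_threshold_rule_on_known_curve(self):
        # verify the four-step rule arithmetic directly on a fabricated curve
        ccc = np.array([1.0, 1.0, 0.7])
        c_max = ccc.max()
        c_thr = c_max * 0.999
        passing = [k for k, c in zip([2, 3, 4], ccc) if c >= c_thr]
        sel = CccSelection(
            k_range=np.array([2, 3, 4]), ccc_by_k=ccc, q=0.999,
            c_max=c_max, c_thr=c_thr, k_hat=max(passing), consensus_results=[],
        )
        assert sel.k_hat == 3
        assert sel.c_thr == pytest.approx(0.999)

    def test_all_equal_curve_selects_largest(self, noiseless_dataset):
        # every k perfectly stable on exact-rank data up to the true rank
        sel = ccc_select(noiseless_dataset.X, [2, 3], n_runs=4, config=FAST_KL)
        assert sel.ccc_by_k[sel.k_hat == sel.k_range].min() >= sel.c_thr

    def test_recovers_planted_rank(self):
        ds = generate(SyntheticSpec(k0=3, m=60, n=150, seed=6))
        sel = ccc_select(ds.X, range(2, 7), n_runs=10, seed=0)
        assert sel.k_hat == 3

    def test_invalid_q_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            ccc_select(small_dataset.X, [2, 3], q=1.5)


class TestBcv:
    def test_noiseless_rank3_error_minimal_at_three(self, noiseless_dataset):
        est = bcv(noiseless_dataset.X, range(1, 7), seed=0)
        i = list(est.k_range).index(3)
        assert est.curve[i] <= est.curve.min() + 1e-9

    def test_deterministic_given_seed(self, small_dataset):
        a = bcv(small_dataset.X, range(1, 6), seed=4)
        b = bcv(small_dataset.X, range(1, 6), seed=4)
        assert a.k_hat == b.k_hat
        np.testing.assert_array_equal(a.curve, b.curve)

    def test_fold_size_vs_k_guard(self):
        X = np.random.default_rng(0).uniform(size=(8, 8))
        with pytest.raises(ValueError):
            bcv(X, range(1, 7), seed=0)

    def test_near_planted_rank_on_noisy_data(self):
        ds = generate(SyntheticSpec(k0=5, seed=2))
        est = bcv(ds.X, range(1, 11), seed=0)
        assert abs(est.k_hat - 5) <= 1
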