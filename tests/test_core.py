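import numpy as np
import pytest

from mifdr import (DataValidationError, PermutationNull, estimate_fdr,
                   max_features, minimize_fdr_at_n, precompute_counts)


class TestPrecomputeCounts:
    def test_naive_recount_oracle(self):
        rng = np.random.default_rng(51)
        d = np.round(rng.normal(size=20), 1)  # rounding manufactures ties
        d_hat = np.round(rng.normal(size=(3, 20)), 1)
        null = PermutationNull.from_d_hat(d_hat)
        counts = precompute_counts(d, null, 20)
        d_sorted = np.sort(d)
        m = 20
        for k in range(21):
            up = d_sorted[m - 1 - k] if k < m else -np.inf
            low = d_sorted[k] if k < m else np.inf
            assert counts.tp_pos[k] == np.sum(d > up)
            assert counts.tp_neg[k] == np.sum(d < low)
            for b in range(3):
                assert counts.fp_pos[k, b] == np.sum(d_hat[b] > up)
                assert counts.fp_neg[k, b] == np.sum(d_hat[b] < low)

    def test_distinct_values_give_identity_tp(self):
        d = np.linspace(-2, 2, 15)
        null = PermutationNull.from_d_hat(np.zeros((1, 15)))
        counts = precompute_counts(d, null, 10)
        np.testing.assert_array_equal(counts.tp_pos, np.arange(11))
        np.testing.assert_array_equal(counts.tp_neg, np.arange(11))

    def test_monotone_in_k(self, make_instance):
        rng = np.random.default_rng(52)
        d, null, _, _ = make_instance(rng)
        counts = precompute_counts(d, null, len(d))
        assert np.all(np.diff(counts.tp_pos) >= 0)
        assert np.all(np.diff(counts.tp_neg) >= 0)
        assert np.all(np.diff(counts.fp_pos, axis=0) >= 0)
        assert np.all(np.diff(counts.fp_neg, axis=0) >= 0)


class TestMinimizeFdrAtN:
    def test_matches_brute_force_scan(self, make_instance, oracle_min_split):
        rng = np.random.default_rng(53)
        checked = 0
        for _ in range(40):
            d, null, pi0, _ = make_instance(rng)
            n_total = int(rng.integers(1, len(d) + 1))
            expected = oracle_min_split(d, null, pi0, n_total)
            if expected is None:
                continue
            res = minimize_fdr_at_n(d, null, pi0, n_total)
            assert (res.n_pos, res.fdr) == expected
            assert res.n_pos + res.n_neg == n_total
            checked += 1
        assert checked >= 30

    def test_result_bounds_every_split(self, make_instance):
        rng = np.random.default_rng(54)
        d, null, pi0, _ = make_instance(rng)
        n_total = max(1, len(d) // 2)
        res = minimize_fdr_at_n(d, null, pi0, n_total)
        for a in range(n_total + 1):
            try:
                est = estimate_fdr(d, null, pi0, a, n_total - a)
            except DataValidationError:
                continue
            assert res.fdr <= est.fdr

    def test_all_positive_d_picks_positive_side_only(self):
        d = np.arange(1.0, 11.0)
        # permuted mass sits between the observed values: calling negatives
        # only adds false positives, so the minimizer is (N, 0)
        rng = np.random.default_rng(55)
        null = PermutationNull.from_d_hat(rng.uniform(1.5, 2.5, size=(4, 10)))
        for n_total in (1, 2, 4):
            res = minimize_fdr_at_n(d, null, 1.0, n_total)
            assert (res.n_pos, res.n_neg) == (n_total, 0)

    def test_n_equals_one_two_option_scan(self):
        d = np.array([-1.0, 0.2, 3.0])
        # no permuted value beyond 0.2 on the positive side or below -1 on the
        # negative side, but plenty below 0.2: option (1, 0) is clean, (0, 1)
        # saturates
        null = PermutationNull.from_d_hat(np.array([[0.0, 0.0, 0.1],
                                                    [0.1, 0.0, 0.0]]))
        res = minimize_fdr_at_n(d, null, 1.0, 1)
        assert (res.n_pos, res.n_neg) == (1, 0)
        assert res.fdr == 0.0

    def test_called_features_are_the_extremes(self):
        d = np.array([0.5, -2.0, 3.0, 1.0, -0.1])
        null = PermutationNull.from_d_hat(np.zeros((1, 5)))
        res = minimize_fdr_at_n(d, null, 1.0, 3)
        called = set(res.feature_pos) | set(res.feature_neg)
        assert res.n_pos + res.n_neg == 3
        # pos calls are the largest d-values, neg calls the smallest
        assert set(res.feature_pos) == set(np.argsort(d)[::-1][: res.n_pos])
        assert set(res.feature_neg) == set(np.argsort(d)[: res.n_neg])
        assert len(called) == 3

    def test_invariant_to_feature_reordering(self):
        rng = np.random.default_rng(56)
        d = rng.normal(size=14)
        d_hat = rng.normal(size=(3, 14))
        perm = rng.permutation(14)
        r1 = minimize_fdr_at_n(d, PermutationNull.from_d_hat(d_hat), 0.8, 5)
        r2 = minimize_fdr_at_n(d[perm], PermutationNull.from_d_hat(d_hat[:, perm]), 0.8, 5)
        assert (r1.n_pos, r1.n_neg, r1.fdr) == (r2.n_pos, r2.n_neg, r2.fdr)

    def test_out_of_range_n_rejected(self):
        d = np.arange(5.0)
        null = PermutationNull.from_d_hat(np.zeros((1, 5)))
        for bad in (0, 6):
            with pytest.raises(DataValidationError):
                minimize_fdr_at_n(d, null, 1.0, bad)


class TestMaxFeatures:
    def test_matches_brute_force_on_random_instances(self, make_instance,
                                                     oracle_max_features):
        rng = np.random.default_rng(57)
        for _ in range(30):
            d, null, pi0, psi = make_instance(rng)
            expected = oracle_max_features(d, null, pi0, psi)
            res = max_features(d, null, pi0, psi, m_rho=len(d))
            if expected is None:
                assert res is None
            else:
                assert (res.n_total, res.n_pos, res.fdr) == expected

    def test_permissive_cutoff_returns_m_rho(self):
        d = np.linspace(-2, 2, 10)
        null = PermutationNull.from_d_hat(np.zeros((2, 10)) + 0.01)
        res = max_features(d, null, 0.5, 0.999, m_rho=6)
        assert res is not None and res.n_total == 6

    def test_pure_null_returns_none(self):
        # observed d replicated as the null: every region is saturated at 1
        rng = np.random.default_rng(58)
        d = rng.normal(size=20)
        null = PermutationNull.from_d_hat(np.tile(d, (3, 1)))
        assert max_features(d, null, 1.0, 0.05, m_rho=20) is None

    def test_m_rho_clipped_to_m(self):
        d = np.linspace(-1, 1, 8)
        null = PermutationNull.from_d_hat(np.zeros((1, 8)) + 0.001)
        res = max_features(d, null, 1.0, 0.9, m_rho=1000)
        assert res is not None and res.n_total <= 8

    def test_counts_reused_across_scan(self, make_instance):
        # the precomputation is evaluated once and shared, not redone per split
        rng = np.random.default_rng(59)
        d, null, pi0, psi = make_instance(rng)
        counts = precompute_counts(d, null, len(d))
        r1 = max_features(d, null, pi0, psi, m_rho=len(d), counts=counts)
        r2 = max_features(d, null, pi0, psi, m_rho=len(d))
        if r1 is None:
            assert r2 is None
        else:
            assert (r1.n_total, r1.n_pos, r1.fdr) == (r2.n_total, r2.n_pos, r2.fdr)

    def test_invalid_psi_rejected(self):
        d = np.arange(4.0)
        null = PermutationNull.from_d_hat(np.zeros((1, 4)))
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(DataValidationError):
                max_features(d, null, 1.0, bad)
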