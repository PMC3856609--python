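import numpy as np
import pytest
from scipy import stats as sps

from mifdr import (DataValidationError, DegenerateStatisticError,
                   ExpressionDataset, d_values, p_values, ranksum_components,
                   select_s0, t_components)
from mifdr.dstats import s0_objective


def make_dataset(x, y):
    """Two-group dataset from per-feature row blocks x (group X) and y."""
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    values = np.hstack([x, y])
    m, w = values.shape
    return ExpressionDataset(
        values=values,
        feature_ids=[f"g{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(w)],
        labels=np.array(["X"] * x.shape[1] + ["Y"] * y.shape[1], dtype=object),
    )


class TestComponents:
    def test_t_hand_example(self):
        ds = make_dataset([[1.0, 3.0]], [[2.0, 4.0]])
        r, s = t_components(ds)
        assert r[0] == pytest.approx(-1.0)
        assert s[0] == pytest.approx(np.sqrt(2.0))

    def test_t_constant_feature(self):
        ds = make_dataset([[5.0, 5.0]], [[5.0, 5.0]])
        r, s = t_components(ds)
        assert r[0] == 0.0 and s[0] == 0.0

    def test_label_swap_negates_r_keeps_s(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(6, 3)), rng.normal(size=(6, 4))
        r1, s1 = t_components(make_dataset(x, y))
        r2, s2 = t_components(make_dataset(y, x))
        np.testing.assert_allclose(r1, -r2)
        np.testing.assert_allclose(s1, s2)

    def test_ranksum_hand_example(self):
        ds = make_dataset([[1.0, 2.0]], [[3.0, 4.0]])
        r, s = ranksum_components(ds)
        assert r[0] == pytest.approx(-2.0)  # ranks {1,2} sum 3, minus 2*5/2
        assert s == pytest.approx(np.sqrt(2 * 2 * 5 / 12.0))

    def test_ranksum_symmetric_multisets(self):
        ds = make_dataset([[1.0, 2.0, 7.0]], [[7.0, 1.0, 2.0]])
        r, _ = ranksum_components(ds)
        assert r[0] == 0.0  # identical multisets with average-rank ties

    def test_ranksum_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        r1, s1 = ranksum_components(make_dataset(x, y))
        r2, s2 = ranksum_components(make_dataset(np.exp(x), np.exp(y)))
        np.testing.assert_allclose(r1, r2)
        assert s1 == s2


class TestSelectS0:
    @staticmethod
    def naive_objective(r, s, c, n_bins=100):
        """Slow per-bin np.median implementation of the dispersion criterion."""
        m = len(s)
        nb = max(1, min(n_bins, m // 2))
        size = m // nb
        order = np.argsort(s, kind="stable")[: nb * size]
        mads = []
        for j in range(nb):
            idx = order[j * size : (j + 1) * size]
            d = r[idx] / (s[idx] + c)
            mads.append(np.median(np.abs(d - np.median(d))))
        mads = np.asarray(mads)
        if mads.mean() <= 0:
            return np.inf
        return mads.std() / mads.mean()

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = int(rng.integers(4, 40))
            r = rng.normal(size=m)
            s = np.abs(rng.normal(size=m)) + 0.01
            cands = np.unique(np.concatenate(([0.0], s)))
            naive = np.array([self.naive_objective(r, s, c) for c in cands])
            assert select_s0(r, s) == cands[int(np.argmin(naive))]

    def test_vectorized_objective_agrees_with_naive(self):
        rng = np.random.default_rng(12)
        r = rng.normal(size=30)
        s = np.abs(rng.normal(size=30)) + 0.05
        cands = np.unique(np.concatenate(([0.0], s)))
        vec = s0_objective(r, s, cands)
        naive = np.array([self.naive_objective(r, s, c) for c in cands])
        np.testing.assert_allclose(vec, naive, rtol=0, atol=0)

    def test_two_feature_brute_case(self):
        r = np.array([1.0, 10.0])
        s = np.array([1.0, 10.0])
        cands = np.unique(np.concatenate(([0.0], s)))
        naive = np.array([self.naive_objective(r, s, c) for c in cands])
        assert select_s0(r, s) == cands[int(np.argmin(naive))]

    def test_constant_spread_is_deterministic_pool_member(self):
        r = np.array([1.0, -2.0, 0.5, 3.0])
        s = np.full(4, 2.0)
        s0 = select_s0(r, s)
        assert s0 in (0.0, 2.0)
        assert select_s0(r, s) == s0  # deterministic

    def test_degenerate_spread_raises(self):
        with pytest.raises(DegenerateStatisticError, match="degenerate spread"):
            select_s0(np.array([1.0, 0.0]), np.zeros(2))

    def test_all_zero_r_and_s_yields_zero(self):
        assert select_s0(np.zeros(3), np.zeros(3)) == 0.0


class TestDValues:
    def test_direct_arithmetic(self):
        np.testing.assert_allclose(
            d_values(np.array([1.0, -2.0]), np.ones(2), 1.0), [0.5, -1.0]
        )

    def test_zero_denominator_raises(self):
        with pytest.raises(DegenerateStatisticError):
            d_values(np.array([1.0]), np.zeros(1), 0.0)

    def test_t_scale_invariance_with_reselected_s0(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=(20, 4)), rng.normal(size=(20, 4))
        ds1 = make_dataset(x, y)
        ds2 = make_dataset(5.0 * x, 5.0 * y)
        r1, s1 = t_components(ds1)
        r2, s2 = t_components(ds2)
        np.testing.assert_allclose(r2, 5.0 * r1)
        np.testing.assert_allclose(s2, 5.0 * s1)
        d1 = d_values(r1, s1, select_s0(r1, s1))
        d2 = d_values(r2, s2, select_s0(r2, s2))
        np.testing.assert_allclose(d1, d2, rtol=1e-9)


class TestPValues:
    def test_identical_groups_give_p_one(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        assert p_values(ds, "t_two_sided")[0] == pytest.approx(1.0)

    def test_t_p_matches_independent_cdf(self):
        ds = make_dataset([[1.0, 3.0]], [[2.0, 4.0]])
        p = p_values(ds, "t_two_sided")[0]
        assert p == pytest.approx(2 * sps.t.sf(abs(-1.0 / np.sqrt(2)), 2))

    def test_t_p_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=(40, 5)), rng.normal(size=(40, 6))
        ds = make_dataset(x, y)
        ref = sps.ttest_ind(x, y, axis=1, equal_var=True).pvalue
        np.testing.assert_allclose(p_values(ds, "t_two_sided"), ref)

    def test_ranksum_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(15)
        x = np.round(rng.normal(size=(25, 5)), 1)  # rounding forces ties
        y = np.round(rng.normal(size=(25, 5)), 1)
        ds = make_dataset(x, y)
        p = p_values(ds, "ranksum_two_sided")
        ref = [
            sps.mannwhitneyu(x[i], y[i], alternative="two-sided",
                             method="asymptotic", use_continuity=False).pvalue
            for i in range(25)
        ]
        np.testing.assert_allclose(p, ref)

    def test_one_sided_le_two_sided_in_favored_direction(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(1.0, 1.0, size=(30, 4)), rng.normal(size=(30, 4))
        ds = make_dataset(x, y)
        one, two = p_values(ds, "t_one_sided"), p_values(ds, "t_two_sided")
        r, _ = t_components(ds)
        favored = r > 0
        assert np.all(one[favored] <= two[favored])

    def test_unknown_test_rejected(self):
        ds = make_dataset([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(DataValidationError):
            p_values(ds, "wilcoxon_signed")
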