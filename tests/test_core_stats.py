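"""Oracle and property tests for the statistical primitives."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from oescreen.core_stats import (
    CapacityError,
    CollinearityError,
    DegenerateInputError,
    bh_adjust,
    fisher_exact_2x2,
    fisher_exact_rxc,
    hypergeom_upper_tail,
    iqr_outlier_mask,
    ols_residualize,
    pearson_corr_matrix,
    permutation_corr_test,
    spearman_rho,
    t_from_summary,
    welch_t,
    zscore_vector,
)


class TestSpearman:
    @pytest.mark.parametrize("x, y, expected", [
        ((1, 2, 3, 4), (2, 4, 6, 8), 1.0),
        ((1, 2, 3, 4), (8, 6, 4, 2), -1.0),
        # hand Pearson on average ranks (1, 2.5, 2.5, 4) vs (1, 2, 3, 4)
        ((1, 2, 2, 4), (10, 20, 30, 40), 4.5 / math.sqrt(4.5 * 5.0)),
    ])
    def test_known_values(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        r = spearman_rho(x, y)
        assert r == pytest.approx(spearman_rho(y, x))
        assert -1.0 <= r <= 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestPermutationTest:
    def test_exhaustive_small_n_is_exact(self):
        # all 6 permutations of 3 elements; |rho|=1 for identity and reversal
        res = permutation_corr_test([1, 2, 3], [1, 2, 3])
        assert res.exhaustive
        assert res.p_value == pytest.approx(2 / 6)
        assert res.n_permutations == 6

    def test_add_one_smoothing_lower_bound(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = permutation_corr_test(x, y, n_perm=200, seed=3, mode="monte-carlo")
        assert res.p_value >= 1 / 201

    def test_seed_reproducibility(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = permutation_corr_test(x, y, n_perm=2000, seed=5)
        b = permutation_corr_test(x, y, n_perm=2000, seed=5)
        assert a.p_value == b.p_value and a.rho == b.rho

    def test_exhaustive_matches_monte_carlo(self, rng):
        """Exhaustive p agrees with sampling within 3 binomial SEs."""
        x, y = rng.normal(size=6), rng.normal(size=6)
        exact = permutation_corr_test(x, y, mode="exhaustive")
        mc = permutation_corr_test(x, y, n_perm=10_000, seed=1,
                                   mode="monte-carlo")
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1e-4

    def test_one_sided_upper_tail(self):
        res = permutation_corr_test([1, 2, 3, 4], [1, 2, 3, 4], sided="one")
        assert res.p_value == pytest.approx(1 / 24)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.049, 0.05), (0.015, 0.05, 0.05)),
        ((1.0,), (1.0,)),
    ])
    def test_step_up_formula_by_hand(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_independent_step_up_oracle(self, p):
        """q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j)."""
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1 + 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTTests:
    def test_identical_groups_null(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separation_limit(self):
        eps = 1e-6
        a = np.array([0, 0, 0, 0]) + eps * np.array([1, -1, 1, -1])
        b = np.array([1, 1, 1, 1]) + eps * np.array([-1, 1, -1, 1])
        assert welch_t(a, b).p_value < 1e-10

    def test_summary_equals_raw_welch(self, rng):
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 1.5, 11)
        raw = welch_t(a, b)
        summ = t_from_summary(a.mean(), a.std(ddof=1), len(a),
                              b.mean(), b.std(ddof=1), len(b))
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12)
        assert raw.df == pytest.approx(summ.df, rel=1e-12)

    def test_matches_label_permutation_oracle(self, rng):
        """Welch p approximates the group-label permutation p at n>=20."""
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 20)
        p_t = welch_t(a, b).p_value
        pooled = np.concatenate([a, b])
        t_obs = abs(stats.ttest_ind(a, b, equal_var=False).statistic)
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            t = abs(stats.ttest_ind(pooled[:20], pooled[20:],
                                    equal_var=False).statistic)
            count += t >= t_obs
        p_perm = (1 + count) / (n_perm + 1)
        se = math.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) <= 4 * se + 0.005

    def test_equal_means_from_summary(self):
        res = t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_rejects_degenerate_summaries(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 0.0, 10, 2.0, 1.0, 10)


class TestFisherExact:
    def test_trivial_and_enumerated_values(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)
        # both extreme diagonal tables have probability 1/C(20,10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]).p_value == pytest.approx(
            2 / 184756, rel=1e-12)

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(40):
            t = rng.integers(0, 12, (2, 2))
            t[t.sum(axis=1) == 0, 0] += 1
            if (t.sum(axis=0) == 0).any():
                t[0, t.sum(axis=0) == 0] += 1
            ours = fisher_exact_2x2(t).p_value
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_doubling_rule_option(self):
        p_double = fisher_exact_2x2([[9, 7], [3, 12]], rule="double").p_value
        assert 0 < p_double <= 1
        assert p_double >= fisher_exact_2x2([[9, 7], [3, 12]]).p_value - 1e-12


class TestFreemanHalton:
    def test_uniform_table_is_modal(self):
        assert fisher_exact_rxc([[1, 1, 1], [1, 1, 1]]).p_value == pytest.approx(1.0)

    def test_zero_column_reduces_to_2x2(self):
        t3 = [[4, 3, 0], [2, 6, 0]]
        t2 = [[4, 3], [2, 6]]
        assert fisher_exact_rxc(t3).p_value == pytest.approx(
            fisher_exact_2x2(t2).p_value, rel=1e-12)

    def test_matches_brute_force_enumeration_oracle(self, rng):
        """Independent oracle: iterate every margin-consistent table directly."""
        for _ in range(15):
            t = rng.integers(0, 6, (2, 3))
            t = t + 1  # keep margins positive
            ours = fisher_exact_rxc(t).p_value
            r1 = int(t[0].sum())
            cols = t.sum(axis=0)
            n = int(t.sum())
            denom = math.comb(n, r1)

            def prob(a, b, c):
                return Fraction(math.comb(cols[0], a) * math.comb(cols[1], b)
                                * math.comb(cols[2], c), denom)

            p_obs = prob(*t[0])
            total = Fraction(0)
            p = Fraction(0)
            for a in range(cols[0] + 1):
                for b in range(cols[1] + 1):
                    c = r1 - a - b
                    if c < 0 or c > cols[2]:
                        continue
                    q = prob(a, b, c)
                    total += q
                    if q <= p_obs:
                        p += q
            assert total == 1  # enumeration covers the whole distribution
            assert ours == pytest.approx(float(p), rel=1e-12)

    def test_capacity_limit(self):
        with pytest.raises(CapacityError):
            fisher_exact_rxc([[100, 100, 50], [60, 40, 30]])


class TestHypergeometric:
    @pytest.mark.parametrize("N, K, n, k, expected", [
        (10, 5, 5, 0, 1.0),            # whole support
        (10, 5, 5, 5, 1 / 252),        # single extreme term
        (10, 4, 5, 3, 66 / 252),       # pmf at 3 plus pmf at 4
    ])
    def test_enumerated_tail_values(self, N, K, n, k, expected):
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(expected, rel=1e-12)

    def test_tail_complement_identity(self):
        p_up = hypergeom_upper_tail(60, 20, 15, 7)
        p_down = float(stats.hypergeom.cdf(6, 60, 20, 15))
        assert p_up + p_down == pytest.approx(1.0, abs=1e-12)

    def test_large_population_uses_survival_function(self):
        p = hypergeom_upper_tail(54675, 2574, 727, 48)
        assert p == pytest.approx(float(stats.hypergeom.sf(47, 54675, 2574, 727)))

    def test_rejects_out_of_support(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 5, 6)


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([3.0, 5.0, 10.0])
        res = ols_residualize(y, np.ones((3, 1)))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_exact_linear_gives_zero_residuals(self):
        x = np.arange(6.0)
        np.testing.assert_allclose(ols_residualize(2 * x + 1, x[:, None]),
                                   0.0, atol=1e-10)

    def test_three_point_hand_solution(self):
        res = ols_residualize([1.0, 2.0, 4.0], [[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(res, [1 / 6, -2 / 6, 1 / 6], atol=1e-12)

    def test_orthogonality_to_covariates(self, rng):
        X = rng.normal(size=(30, 3))
        res = ols_residualize(rng.normal(size=30), X)
        assert abs(res.sum()) < 1e-9
        np.testing.assert_allclose(res @ X, 0.0, atol=1e-8)

    def test_collinear_design_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(CollinearityError):
            ols_residualize(np.ones(5), np.column_stack([x, 2 * x]))


class TestZScore:
    def test_unit_spacing(self):
        np.testing.assert_allclose(zscore_vector([1, 2, 3]), [-1, 0, 1],
                                   atol=1e-12)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=20,
                    unique=True),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_normalized_and_affine_invariant(self, v, a, b):
        assume(np.std(v) > 1e-3)
        z = zscore_vector(v)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(zscore_vector(a * np.asarray(v) + b), z,
                                   atol=1e-7)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_vector([2.0, 2.0, 2.0])


class TestIqrOutliers:
    def test_zero_iqr_flags_any_deviation(self):
        mask = iqr_outlier_mask([1, 1, 1, 1, 1, 1, 1, 101])
        assert mask.tolist() == [False] * 7 + [True]

    def test_linear_ramp_has_no_outliers(self):
        # Q1=2.75, Q3=6.25 under linear interpolation; fences -2.5 / 11.5
        assert not iqr_outlier_mask([1, 2, 3, 4, 5, 6, 7, 8]).any()

    def test_order_invariance(self, rng):
        v = np.concatenate([rng.normal(size=20), [50.0]])
        perm = rng.permutation(21)
        assert (iqr_outlier_mask(v)[perm] == iqr_outlier_mask(v[perm])).all()


class TestCorrMatrix:
    def test_duplicate_and_negated_rows(self, rng):
        base = rng.normal(size=10)
        X = np.vstack([base, base, -base])
        r = pearson_corr_matrix(X)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_matches_pairwise_scalar_oracle(self, rng):
        X = rng.normal(size=(5, 10))
        r = pearson_corr_matrix(X)
        for i, j in itertools.combinations(range(5), 2):
            assert r[i, j] == pytest.approx(float(stats.pearsonr(X[i], X[j])[0]))

    def test_constant_row_flagged(self, rng):
        X = np.vstack([np.ones(5), rng.normal(size=5)])
        with pytest.raises(DegenerateInputError):
            pearson_corr_matrix(X)
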