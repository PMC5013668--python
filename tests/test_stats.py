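"""Statistical primitives vs independent oracles (scipy, exact rationals,
permutation)."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cfemerge import (
    BetaPosterior,
    beta_binomial_pmf,
    beta_binomial_sf,
    beta_posterior,
    binomial_tail_lower,
    linear_log_regression,
    mdm2_copy_number,
    pearson_test,
    predictive_fold_change,
    two_sample_t,
)


class TestBetaPosterior:
    def test_zero_detections_in_nine_normals(self):
        post = beta_posterior(0, 9)
        assert (post.alpha, post.beta) == (1.0, 10.0)

    def test_no_data_returns_prior(self):
        assert beta_posterior(0, 0) == BetaPosterior(1.0, 1.0)

    def test_conjugate_update(self):
        assert beta_posterior(3, 9) == BetaPosterior(4.0, 7.0)

    def test_detections_cannot_exceed_samples(self):
        with pytest.raises(ValueError):
            beta_posterior(10, 9)

    def test_shapes_must_be_positive(self):
        with pytest.raises(ValueError):
            BetaPosterior(0.0, 1.0)


class TestBetaBinomial:
    def test_zero_detection_predictive_closed_form(self):
        """P(0 of 14 | Beta(1,10)) = 10/24: the closed form beta/(beta+n)
        for a Beta(1, beta) posterior."""
        p = beta_binomial_pmf(0, 14, BetaPosterior(1, 10))
        assert p == pytest.approx(10 / 24, abs=1e-12)

    def test_uniform_prior_predictive_is_discrete_uniform(self):
        # brute-force integral: with Beta(1,1) every k in 0..n is equally likely
        post = BetaPosterior(1, 1)
        for k in range(6):
            assert beta_binomial_pmf(k, 5, post) == pytest.approx(1 / 6, abs=1e-12)
        assert beta_binomial_sf(5, 5, post) == pytest.approx(1 / 6, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(1, 200),
        st.floats(0.1, 50), st.floats(0.1, 50),
    )
    def test_pmf_normalises(self, n, a, b):
        post = BetaPosterior(a, b)
        total = sum(beta_binomial_pmf(k, n, post) for k in range(n + 1))
        assert abs(total - 1.0) < 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 100), st.floats(0.5, 30))
    def test_alpha_one_closed_form(self, n, b):
        """pmf(0; n, Beta(1, b)) = b/(b+n) exactly."""
        p = beta_binomial_pmf(0, n, BetaPosterior(1.0, b))
        assert p == pytest.approx(b / (b + n), rel=1e-12)

    @pytest.mark.parametrize("k,n,a,b", [(0, 14, 1, 10), (12, 25, 1, 10),
                                         (3, 7, 2.5, 4.0)])
    def test_matches_scipy_betabinom(self, k, n, a, b):
        ours = beta_binomial_pmf(k, n, BetaPosterior(a, b))
        ref = sps.betabinom.pmf(k, n, a, b)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_sf_complementarity(self):
        post = BetaPosterior(1, 10)
        assert beta_binomial_sf(0, 25, post) == pytest.approx(1.0, abs=1e-9)
        for k in range(1, 26):
            cdf = sum(beta_binomial_pmf(i, 25, post) for i in range(k))
            assert beta_binomial_sf(k, 25, post) + cdf == pytest.approx(1.0, abs=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            beta_binomial_pmf(5, 4, BetaPosterior(1, 1))


class TestFoldChange:
    def test_basic_ratios(self):
        assert predictive_fold_change(0.4, 0.4) == 1
        assert predictive_fold_change(0.4, 0.004) == pytest.approx(100)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            predictive_fold_change(0.4, 0.0)

    def test_emergence_fold_change_against_scipy_oracle(self):
        """Baseline (0/14) vs treatment (12/25) predictive fold change
        under the Beta(1,10) posterior, checked against scipy's
        beta-binomial."""
        post = BetaPosterior(1, 10)
        fc = predictive_fold_change(
            beta_binomial_pmf(0, 14, post), beta_binomial_pmf(12, 25, post)
        )
        oracle = sps.betabinom.pmf(0, 14, 1, 10) / sps.betabinom.pmf(12, 25, 1, 10)
        assert fc == pytest.approx(oracle, rel=1e-9)


class TestBinomialTail:
    def test_transversion_test_printed_value(self):
        """P(X <= 3 | n=15, p=1/2) = 576/32768 = 0.017578125."""
        p = binomial_tail_lower(3, 15, 0.5)
        assert p == float(Fraction(576, 32768))
        assert p == pytest.approx(0.01757812, abs=1e-8)

    def test_trivial_tails(self):
        assert binomial_tail_lower(15, 15, 0.5) == 1.0
        assert binomial_tail_lower(0, 4, 0.5) == pytest.approx(1 / 16)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 30).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_exact_rational_oracle_at_half(self, nk):
        """Agreement with the big-integer rational sum C(n,i)/2^n."""
        n, k = nk
        oracle = Fraction(sum(math.comb(n, i) for i in range(k + 1)), 2**n)
        assert binomial_tail_lower(k, n, 0.5) == float(oracle)

    @pytest.mark.parametrize("k,n,p", [(2, 10, 0.3), (7, 20, 0.6)])
    def test_matches_scipy_for_general_p(self, k, n, p):
        assert binomial_tail_lower(k, n, p) == pytest.approx(
            sps.binom.cdf(k, n, p), rel=1e-9
        )


class TestPearson:
    def test_perfect_positive_and_negative(self):
        res = pearson_test([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.ci95 == (1.0, 1.0)
        res = pearson_test([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 25))
        res = pearson_test(x, y)
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci95[0] == pytest.approx(lo, abs=1e-9)
        assert res.ci95[1] == pytest.approx(hi, abs=1e-9)

    def test_fisher_ci_contains_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = pearson_test(x, y)
        assert res.ci95[0] < res.r < res.ci95[1]
        assert res.df == 28

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])


class TestLinearLogRegression:
    def test_noise_free_line_recovered_exactly(self):
        burdens = [0.01, 0.1, 1, 10]  # logs -2,-1,0,1
        ct = [10 + 30 * math.log10(b) for b in burdens]
        fit = linear_log_regression(ct, burdens)
        assert fit.slope == pytest.approx(30, abs=1e-9)
        assert fit.intercept == pytest.approx(10, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.significant()

    def test_constant_response_has_zero_slope(self):
        fit = linear_log_regression([5, 5, 5, 5], [0.1, 1, 10, 100])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)
        assert not fit.significant()

    def test_non_positive_burden_instructs_caller(self):
        with pytest.raises(ValueError, match="detected"):
            linear_log_regression([1, 2, 3], [0.0, 1.0, 2.0])

    def test_f_equals_t_squared_and_r2_equals_pearson_r2(self):
        rng = np.random.default_rng(7)
        b = 10 ** rng.uniform(-1, 1.5, size=40)
        ct = 10 + 30 * np.log10(b) + rng.normal(0, 10, size=40)
        fit = linear_log_regression(ct, b)
        assert fit.f_stat == pytest.approx(fit.slope_t**2, abs=1e-9)
        corr = pearson_test(np.log10(b), ct)
        assert fit.r_squared == pytest.approx(corr.r**2, rel=1e-9)
        assert fit.slope_p == pytest.approx(corr.p_two_sided, rel=1e-6)
        # OLS slope = r * sd(y)/sd(x)
        assert fit.slope == pytest.approx(
            corr.r * np.std(ct, ddof=1) / np.std(np.log10(b), ddof=1), rel=1e-9
        )


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_separated_groups(self):
        a = [1000.0, 1000.1, 1000.2, 999.9]
        b = [0.0, 0.1, 0.2, -0.1]
        res = two_sample_t(a, b)
        assert res["p_two_sided"] < 1e-6
        assert res["mean_a"] == pytest.approx(np.mean(a))
        assert res["sd_b"] == pytest.approx(np.std(b, ddof=1))

    def test_group_size_validated(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_matches_permutation_oracle(self):
        """Welch p on an 8+8 toy agrees with a permutation distribution of
        the Welch statistic within Monte-Carlo error."""
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.2, 1.0, 8)
        res = two_sample_t(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 4000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t_perm = sps.ttest_ind(perm[:8], perm[8:], equal_var=False).statistic
            count += abs(t_perm) >= abs(res["t"])
        p_perm = count / n_perm
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-4
        assert abs(res["p_two_sided"] - p_perm) < 5 * se + 0.02


class TestCopyNumber:
    def test_calibrator_equal_sample_is_diploid(self):
        res = mdm2_copy_number([25.0, 25.1, 24.9], [23.0, 23.1, 22.9], 2.0)
        assert res.delta_delta_ct == pytest.approx(0.0, abs=1e-12)
        assert res.copy_number == pytest.approx(2.0)
        assert not res.amplified

    def test_ddct_minus_two_is_eight_copies_amplified(self):
        res = mdm2_copy_number([21.0] * 3, [23.0] * 3, 0.0)
        assert res.delta_delta_ct == pytest.approx(-2.0)
        assert res.copy_number == pytest.approx(8.0)
        assert res.amplified

    def test_strict_five_copy_rule(self):
        res = mdm2_copy_number([21.75] * 3, [23.0] * 3, 0.0)  # ddCt = -1.25
        assert res.copy_number == pytest.approx(2 * 2**1.25)
        assert res.copy_number < 5 and not res.amplified

    def test_short_replicates_warn_and_empty_errors(self):
        with pytest.warns(UserWarning, match="triplicates"):
            mdm2_copy_number([21.0, 21.2], [23.0] * 3, 0.0)
        with pytest.raises(ValueError):
            mdm2_copy_number([], [23.0] * 3, 0.0)
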