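"""Unit tests for species-level Ne estimation primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from necomp import (
    InvalidInputError,
    MutationRateEstimate,
    DiversityEstimate,
    binomial_rate_ci,
    estimate_ne,
    fit_lognormal,
    geometric_mean,
    mean_pi_across_populations,
    paired_log_t_test,
    propagate_ne_ci,
    rank_correlation,
    weighted_mean_mu,
)


def wilson_oracle(k, n, level=0.95):
    """Closed-form Wilson score interval, written independently."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - level) / 2)
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    return center - half, center + half


class TestBinomialRateCI:
    def test_zero_successes_lower_bound_is_zero(self):
        low, high = binomial_rate_ci(0, 1000, 0.95)
        assert low == 0.0
        assert 0 < high < 1

    @pytest.mark.parametrize(
        "k,n",
        [(50, 100), (5, 2 * 10**8), (1, 10**6), (999, 1000)],
    )
    def test_matches_closed_form_wilson(self, k, n):
        low, high = binomial_rate_ci(k, n, 0.95)
        olow, ohigh = wilson_oracle(k, n, 0.95)
        assert low == pytest.approx(olow, rel=1e-9, abs=1e-15)
        assert high == pytest.approx(ohigh, rel=1e-9, abs=1e-15)

    def test_rare_event_interval_asymmetric_and_positive(self):
        low, high = binomial_rate_ci(5, 2 * 10**8, 0.95)
        p = 5 / 2e8
        assert 0 < low < p < high
        assert (high - p) > (p - low)  # right-skewed for rare events

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            binomial_rate_ci(1, 0)
        with pytest.raises(InvalidInputError):
            binomial_rate_ci(-1, 10)
        with pytest.raises(InvalidInputError):
            binomial_rate_ci(11, 10)
        with pytest.raises(InvalidInputError):
            binomial_rate_ci(1, 10, level=1.0)

    def test_clopper_pearson_swap_available(self):
        p = 5 / 1000
        w = binomial_rate_ci(5, 1000, method="wilson")
        cp = binomial_rate_ci(5, 1000, method="beta")
        assert cp != w
        assert cp[0] < p < cp[1]
        assert cp[1] - cp[0] >= w[1] - w[0]  # exact interval conservative


def _mre(rate, effort, se=None, species="sp1"):
    ci = None if se is None else (rate - 1.96 * se, rate + 1.96 * se)
    return MutationRateEstimate(
        species_id=species,
        rate=rate,
        ci_low=None if ci is None else max(ci[0], 0.0),
        ci_high=None if ci is None else ci[1],
        effort=effort,
    )


class TestWeightedMeanMu:
    def test_single_estimate_identity(self):
        e = _mre(1e-8, 10, se=1e-9)
        assert weighted_mean_mu([e]) is e

    def test_effort_weighted_rate(self):
        out = weighted_mean_mu([_mre(1e-8, 10), _mre(2e-8, 30)])
        assert out.rate == pytest.approx(1.75e-8)
        assert out.effort == 40

    def test_se_propagation(self):
        # sqrt(10^2 (2e-9)^2 + 30^2 (1e-9)^2)/40 computed independently
        out = weighted_mean_mu(
            [_mre(1e-8, 10, se=2e-9), _mre(2e-8, 30, se=1e-9)]
        )
        se_expected = math.sqrt(100 * (2e-9) ** 2 + 900 * 1e-18) / 40
        assert se_expected == pytest.approx(9.0138e-10, rel=1e-4)
        half = (out.ci_high - out.ci_low) / 2
        assert half == pytest.approx(1.96 * se_expected, rel=1e-9)

    def test_equal_efforts_reduce_to_unweighted_mean(self):
        ests = [_mre(r, 7.0, se=1e-9) for r in (1e-8, 3e-8, 5e-8)]
        out = weighted_mean_mu(ests)
        assert out.rate == pytest.approx(3e-8)
        se = (out.ci_high - out.ci_low) / (2 * 1.96)
        assert se <= 1e-9 + 1e-18  # combined SE <= max individual SE

    def test_ci_floored_at_zero(self):
        out = weighted_mean_mu([_mre(1e-9, 5, se=1e-8), _mre(2e-9, 5, se=1e-8)])
        assert out.ci_low == 0.0

    def test_variance_imputed_for_ci_less_study(self):
        out = weighted_mean_mu([_mre(1e-8, 10, se=2e-9), _mre(2e-8, 10)])
        # imputed SE = 2e-9 for the second study
        se = math.sqrt(100 * (2e-9) ** 2 + 100 * (2e-9) ** 2) / 20
        assert (out.ci_high - out.ci_low) / 2 == pytest.approx(
            1.96 * se, rel=1e-9
        )

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            weighted_mean_mu([])
        with pytest.raises(InvalidInputError):
            weighted_mean_mu([_mre(1e-8, 1), _mre(1e-8, 1, species="sp2")])


class TestMeanPi:
    @pytest.mark.parametrize(
        "pis,expected",
        [([0.01], 0.01), ([0.01, 0.03], 0.02), ([0.004, 0.006, 0.008], 0.006)],
    )
    def test_arithmetic_mean(self, pis, expected):
        ests = [
            DiversityEstimate(species_id="sp1", pi=p, population_label=str(i))
            for i, p in enumerate(pis)
        ]
        assert mean_pi_across_populations(ests).pi == pytest.approx(expected)

    def test_site_class_bookkeeping(self):
        a = DiversityEstimate("sp1", 0.01, site_class="synonymous")
        b = DiversityEstimate("sp1", 0.02, site_class="genome_wide")
        assert mean_pi_across_populations([a, b]).site_class == "genome_wide"
        assert mean_pi_across_populations([a]).site_class == "synonymous"

    def test_empty_errors(self):
        with pytest.raises(InvalidInputError):
            mean_pi_across_populations([])


class TestEstimateNe:
    @pytest.mark.parametrize(
        "pi,x,mu,expected",
        [(0.004, 2, 1e-8, 100_000), (0.002, 1, 1e-9, 1_000_000)],
    )
    def test_point_estimates(self, pi, x, mu, expected):
        assert estimate_ne(pi, x, mu) == pytest.approx(expected)

    @given(
        pi=st.floats(1e-6, 0.5),
        mu=st.floats(1e-10, 1e-6),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_pi_inverse_in_mu(self, pi, mu, k):
        base = estimate_ne(pi, 2, mu)
        assert estimate_ne(k * pi, 2, mu) == pytest.approx(k * base, rel=1e-12)
        assert estimate_ne(pi, 2, k * mu) == pytest.approx(base / k, rel=1e-12)

    @given(
        ne=st.floats(1e3, 1e8),
        mu=st.floats(1e-10, 1e-7),
        ploidy=st.sampled_from([1, 2]),
    )
    @settings(max_examples=100, deadline=None)
    def test_inverts_equilibrium_diversity(self, ne, mu, ploidy):
        pi = 2 * ploidy * ne * mu
        assert estimate_ne(pi, ploidy, mu) == pytest.approx(ne, rel=1e-12)

    def test_mu_zero_errors(self):
        with pytest.raises(InvalidInputError):
            estimate_ne(0.01, 2, 0.0)


class TestPropagateNeCI:
    def test_monotone_inversion(self):
        lo, hi = propagate_ne_ci(0.004, 2, (0.5e-8, 2e-8))
        assert lo == pytest.approx(50_000)
        assert hi == pytest.approx(200_000)

    def test_degenerate_ci(self):
        lo, hi = propagate_ne_ci(0.004, 2, (1e-8, 1e-8))
        assert lo == hi == pytest.approx(100_000)

    @given(
        pi=st.floats(1e-5, 0.1),
        mu_lo=st.floats(1e-10, 1e-8),
        width=st.floats(1.0, 10.0),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_brackets_any_interior_mu(self, pi, mu_lo, width, frac):
        mu_hi = mu_lo * width
        mu_mid = mu_lo + frac * (mu_hi - mu_lo)
        lo, hi = propagate_ne_ci(pi, 2, (mu_lo, mu_hi))
        ne_mid = estimate_ne(pi, 2, mu_mid)
        assert lo <= ne_mid * (1 + 1e-12) and ne_mid <= hi * (1 + 1e-12)

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            propagate_ne_ci(0.01, 2, (0.0, 1e-8))
        with pytest.raises(InvalidInputError):
            propagate_ne_ci(0.01, 2, (2e-8, 1e-8))


class TestSmallStats:
    @pytest.mark.parametrize(
        "values,expected",
        [([4, 9], 6.0), ([7.3], 7.3), ([1, 10, 100], 10.0)],
    )
    def test_geometric_mean(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            geometric_mean([1.0, 0.0])

    def test_paired_t_identical_samples(self):
        t, df, p = paired_log_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_paired_t_constant_nonzero_difference_errors(self):
        with pytest.raises(InvalidInputError):
            paired_log_t_test([2.0, 4.0], [1.0, 2.0])

    def test_paired_t_matches_manual_computation(self):
        a = [0.01, 0.02, 0.005, 0.04, 0.012]
        b = [0.012, 0.018, 0.007, 0.03, 0.02]
        t, df, p = paired_log_t_test(a, b)
        d = np.log(a) - np.log(b)
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert df == 4
        assert 0 < p < 1

    def test_lognormal_fit_exact_cases(self):
        e = math.e
        assert fit_lognormal([e, e, e]) == pytest.approx((1.0, 0.0))
        meanlog, _ = fit_lognormal([1.0, e**2])
        assert meanlog == pytest.approx(1.0)

    def test_lognormal_fit_monte_carlo_recovery(self, rng):
        draws = np.exp(rng.normal(2.0, 0.7, size=10_000))
        meanlog, sdlog = fit_lognormal(draws)
        assert meanlog == pytest.approx(2.0, rel=0.02)
        assert sdlog == pytest.approx(0.7, rel=0.02)

    def test_rank_correlation_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert rank_correlation(x, [2, 4, 8, 16, 32])[0] == pytest.approx(1.0)
        assert rank_correlation(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_rank_correlation_with_tie_matches_brute_force(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [10.0, 30.0, 20.0, 50.0, 40.0]

        def midranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        rho, p = rank_correlation(x, y)
        assert rho == pytest.approx(rho_oracle, rel=1e-12)

    def test_rank_correlation_needs_three(self):
        with pytest.raises(InvalidInputError):
            rank_correlation([1, 2], [3, 4])
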