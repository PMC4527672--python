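import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle import exact_rank_sum_p
from seroclade import (
    Censor,
    CensoredValue,
    CohortError,
    censored_median,
    censored_percentile,
    format_summary,
    rank_sum_test,
    summarize_group,
)
from seroclade.stats import QUANTILE_METHODS


def below(b):
    return CensoredValue(b, Censor.BELOW)


def above(u):
    return CensoredValue(u, Censor.ABOVE)


class TestRankSumTest:
    def test_enumerable_example(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"
        assert not res.significant

    def test_identical_groups_p_one(self):
        res = rank_sum_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == 1.0
        assert not res.significant

    def test_all_censored_same_bound_degenerate(self):
        res = rank_sum_test([below(1.71)] * 10, [below(1.71)] * 10)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_empty_group_is_error(self):
        with pytest.raises(CohortError):
            rank_sum_test([], [1.0])

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = list(rng.lognormal(size=rng.integers(2, 15)))
            b = list(rng.lognormal(size=rng.integers(2, 15)))
            fwd = rank_sum_test(a, b)
            rev = rank_sum_test(b, a)
            assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
            assert fwd.rank_direction == -rev.rank_direction

    def test_oracle_agreement_exact_and_asymptotic_8v8(self):
        """Production p agrees with a from-scratch enumeration of all
        C(16,8) rank assignments: exactly on the exact path; the normal
        approximation tracks the oracle within 0.01 in the decision tail
        (p <= 0.1) and within the largest null atom (~0.046) elsewhere,
        the sharpest bound the discrete null admits."""
        rng = np.random.default_rng(1)
        for _ in range(25):
            a = list(rng.lognormal(size=8))
            b = list(0.5 + rng.lognormal(size=8))
            expected = exact_rank_sum_p(a, b)
            got_exact = rank_sum_test(a, b).p_value  # auto -> exact at n=16
            got_asym = rank_sum_test(a, b, method="asymptotic").p_value
            assert got_exact == pytest.approx(expected, abs=1e-12)
            if expected <= 0.1:
                assert got_asym == pytest.approx(expected, abs=0.01)
            assert got_asym == pytest.approx(expected, abs=0.047)

    def test_oracle_agreement_with_censored_tie_blocks(self):
        """The censored ordering reduces to midranks over tie blocks; the
        asymptotic p must track the enumeration oracle run on equivalent
        numeric codes."""
        a = [below(1.71)] * 4 + [CensoredValue(2.0), CensoredValue(3.0)]
        b = [below(1.71)] * 2 + [CensoredValue(2.5), CensoredValue(4.0), CensoredValue(5.0)]
        codes_a = [0, 0, 0, 0, 1, 3]
        codes_b = [0, 0, 2, 4, 5]
        expected = exact_rank_sum_p(codes_a, codes_b)
        got = rank_sum_test(a, b, method="asymptotic").p_value
        assert got == pytest.approx(expected, abs=0.05)

    @given(
        data=st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=12),
        split=st.integers(min_value=1, max_value=11),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_transform_invariance(self, data, split, scale):
        split = min(split, len(data) - 1)
        a, b = data[:split], data[split:]
        base = rank_sum_test(a, b).p_value
        squared = rank_sum_test([x * x * scale for x in a], [x * x * scale for x in b]).p_value
        assert squared == pytest.approx(base, abs=1e-9)

    def test_censored_standin_invariance(self):
        """p depends only on the ordering, not on where the censor bound sits
        numerically, as long as order relations are unchanged."""
        a = [below(1.71), CensoredValue(2.0), CensoredValue(3.0)]
        b = [CensoredValue(2.5), CensoredValue(4.0), below(1.71)]
        a2 = [below(0.9), CensoredValue(2.0), CensoredValue(3.0)]
        b2 = [CensoredValue(2.5), CensoredValue(4.0), below(0.9)]
        assert rank_sum_test(a, b).p_value == pytest.approx(rank_sum_test(a2, b2).p_value, abs=1e-12)

    def test_exact_value_at_lloq_ranks_above_censored_block(self):
        res = rank_sum_test([below(1.71)] * 5, [CensoredValue(1.71)] * 5)
        assert not res.degenerate
        assert res.rank_direction == 1  # exact values at the bound rank higher

    def test_censored_block_below_every_larger_exact(self):
        # heavy censoring in one group forces an extreme rank split
        res = rank_sum_test([below(1.71)] * 8, [CensoredValue(2.0 + i) for i in range(8)])
        assert res.p_value < 0.001
        assert res.significant


class TestCensoredQuantiles:
    def test_mostly_censored_median_is_censored(self):
        # 41 of 50 below the LLOQ: the median sits in the censored block
        values = [below(1.71)] * 41 + [CensoredValue(2.0 + 0.01 * i) for i in range(9)]
        med = censored_median(values)
        assert med == below(1.71)
        assert med.render() == "<1.71"

    def test_exact_median(self):
        assert censored_median([1, 2, 3]) == CensoredValue(2.0)
        assert censored_median([1, 2, 3, 4]) == CensoredValue(2.5)

    def test_median_equals_p50(self):
        rng = np.random.default_rng(3)
        values = [CensoredValue(x) for x in rng.lognormal(size=31)] + [below(0.1)] * 5
        for method in QUANTILE_METHODS:
            assert censored_percentile(values, 0.5, method=method) == censored_median(values, method=method)

    def test_p2_5_bracket_across_methods(self):
        values = [float(i) for i in range(1, 101)]
        for method in QUANTILE_METHODS:
            v = censored_percentile(values, 0.025, method=method)
            assert not v.is_censored
            assert 1.0 <= v.value <= 4.0

    def test_all_above_censored_percentile(self):
        assert censored_percentile([above(1476)] * 12, 0.975) == above(1476)
        assert censored_percentile([above(1476)] * 12, 0.975).render() == ">1476"

    def test_interpolation_only_between_exact(self):
        # median position falls between a censored and an exact value
        values = [below(1.71), below(1.71), CensoredValue(2.0), CensoredValue(3.0)]
        assert censored_median(values) == below(1.71)

    def test_mixed_bounds_at_position_error(self):
        with pytest.raises(CohortError, match="harmonize"):
            censored_median([below(1.0), below(2.0)])

    def test_empty_and_bad_q(self):
        with pytest.raises(CohortError):
            censored_median([])
        with pytest.raises(CohortError):
            censored_percentile([1.0], 1.0)

    def test_lognormal_percentiles_match_analytic(self):
        rng = np.random.default_rng(11)
        mu, sigma, n = 1.0, 0.5, 1000
        values = [CensoredValue(x) for x in rng.lognormal(mu, sigma, size=n)]
        for q in (0.025, 0.5, 0.975):
            analytic = math.exp(mu + sigma * _norm_ppf(q))
            got = censored_percentile(values, q).value
            # order-statistic Monte-Carlo error band (3 x asymptotic SE)
            dens = _lognorm_pdf(analytic, mu, sigma)
            se = math.sqrt(q * (1 - q) / n) / dens
            assert abs(got - analytic) < 3 * se + 1e-9


def _norm_ppf(q):
    from scipy.stats import norm

    return float(norm.ppf(q))


def _lognorm_pdf(x, mu, sigma):
    return math.exp(-((math.log(x) - mu) ** 2) / (2 * sigma**2)) / (x * sigma * math.sqrt(2 * math.pi))


class TestGroupSummary:
    def test_summary_orders_under_censored_ordering(self, human_shift_cohort):
        s = summarize_group(human_shift_cohort, "H-DE", "bilirubin_like")
        assert s.n == 312
        assert s.p2_5.sort_key() <= s.median.sort_key() <= s.p97_5.sort_key()
        assert s.range_min.sort_key() <= s.p2_5.sort_key()
        assert s.p97_5.sort_key() <= s.range_max.sort_key()

    def test_single_value_group(self, tiny_cohort):
        s = summarize_group(tiny_cohort, "Ch-SL", "bilirubin")
        assert s.median == s.p2_5 == s.p97_5 == s.range_min

    def test_renderer_threshold(self, human_shift_cohort):
        big = summarize_group(human_shift_cohort, "H-DE", "bilirubin_like")
        small = summarize_group(human_shift_cohort, "B-DE", "bilirubin_like")
        assert format_summary(big)["spread"] == f"{big.p2_5.render()}–{big.p97_5.render()}"
        assert format_summary(small)["spread"] == f"{small.range_min.render()}–{small.range_max.render()}"

    def test_no_measurements_error(self, tiny_cohort):
        with pytest.raises(CohortError):
            summarize_group(tiny_cohort, "Rh-DE", "cholesterol")
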