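"""Enrichment statistics: Fisher tests, trimming, draw-and-sum null, binomial."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from psgscan.enrichment import (
    GeneUniverse,
    binomial_direction_test,
    draw_sum_null,
    draw_sum_null_from_lists,
    fisher_set_enrichment,
    trim_background_by_expression,
)


def _hypergeom_tail_bruteforce(k, N, K, n):
    """P(X >= k) by explicit summation of hypergeometric point masses."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x) / comb(N, n)
    return total


class TestFisher:
    def test_worked_example_against_bruteforce(self):
        genes = [f"g{i}" for i in range(1000)]
        uni = GeneUniverse(genes)
        target = set(genes[:50])
        query = set(genes[:5]) | set(genes[500:505])  # 5 hits of 10
        res = fisher_set_enrichment(query, target, uni)
        assert res.overlap == 5
        assert res.fold_enrichment == pytest.approx((5 / 10) / (50 / 1000))  # = 10
        assert res.pvalue == pytest.approx(_hypergeom_tail_bruteforce(5, 1000, 50, 10), rel=1e-9)
        assert res.table == [[5, 5], [45, 945]]

    def test_zero_hits_no_evidence(self):
        genes = [f"g{i}" for i in range(100)]
        uni = GeneUniverse(genes)
        res = fisher_set_enrichment(genes[50:60], genes[:20], uni)
        assert res.fold_enrichment == 0.0
        assert res.pvalue >= 0.5

    def test_target_equals_universe(self):
        genes = [f"g{i}" for i in range(40)]
        uni = GeneUniverse(genes)
        res = fisher_set_enrichment(genes[:10], genes, uni)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        genes = [f"g{i}" for i in range(200)]
        uni = GeneUniverse(genes)
        p1 = fisher_set_enrichment(genes[:20], genes[10:60], uni).pvalue
        renamed = [f"x{i}" for i in range(200)]
        uni2 = GeneUniverse(renamed)
        p2 = fisher_set_enrichment(renamed[:20], renamed[10:60], uni2).pvalue
        assert p1 == p2

    def test_empty_inputs_rejected(self):
        uni = GeneUniverse(["a", "b"])
        with pytest.raises(ValueError):
            fisher_set_enrichment([], ["a"], uni)


class TestExpressionTrim:
    def _uni(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        return GeneUniverse(genes, dict(zip(genes, values)))

    def test_background_inside_reference_range_unchanged(self):
        uni = self._uni(list(range(1, 101)))
        ref = uni.genes  # reference spans everything
        trimmed = trim_background_by_expression(uni, ref, 0.0, 1.0)
        assert len(trimmed) == 100

    def test_outlier_removed(self):
        uni = self._uni(list(range(1, 101)) + [200])
        ref = uni.genes[:100]  # reference expressions 1..100
        trimmed = trim_background_by_expression(uni, ref)
        assert uni.genes[100] not in trimmed.genes

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(2, 1, size=500)
        uni = self._uni(vals)
        ref = list(rng.choice(uni.genes, size=80, replace=False))
        trimmed = trim_background_by_expression(uni, ref)
        ref_vals = [uni.expression[g] for g in ref]
        lo, hi = np.quantile(ref_vals, [0.05, 0.95])
        expected = sum(1 for g in uni.genes if lo <= uni.expression[g] <= hi)
        assert len(trimmed) == expected

    def test_empty_reference_rejected(self):
        uni = self._uni([1.0, 2.0])
        with pytest.raises(ValueError):
            trim_background_by_expression(uni, [])


class TestDrawSumNull:
    def test_no_specials_no_mass_above_zero(self):
        null = draw_sum_null([(100, 0, 10), (50, 0, 5)], mode="exact")
        assert null.tail_probability(1) == 0.0
        sim = draw_sum_null([(100, 0, 10)], rounds=1000, seed=0, mode="simulate")
        assert sim.max_observed == 0

    def test_exact_pmf_normalized_and_mean_identity(self):
        strata = [(200, 20, 30), (150, 10, 25)]
        null = draw_sum_null(strata, mode="exact")
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        expected_mean = sum(d * k / n for n, k, d in strata)
        assert null.mean() == pytest.approx(expected_mean, rel=1e-12)

    @given(st.lists(
        st.tuples(st.integers(20, 200), st.integers(0, 15), st.integers(1, 15)),
        min_size=1, max_size=3))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_exact_mean_identity_property(self, strata):
        null = draw_sum_null(strata, mode="exact")
        expected = sum(d * k / n for n, k, d in strata)
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert null.mean() == pytest.approx(expected, rel=1e-9)

    def test_simulation_approaches_exact_with_rounds(self):
        strata = [(300, 30, 40)]
        exact = draw_sum_null(strata, mode="exact")
        cdf_exact = np.cumsum(exact.pmf)

        def ks(rounds):
            sim = draw_sum_null(strata, rounds=rounds, seed=3, mode="simulate")
            emp = np.searchsorted(sim.samples, exact.support, side="right") / rounds
            return np.max(np.abs(emp - cdf_exact))

        assert ks(100_000) < ks(1_000)

    def test_list_wrapper_matches_counts(self):
        bg = [f"g{i}" for i in range(100)]
        special = bg[:10]
        null = draw_sum_null_from_lists([(bg, special, 20)], rounds=5000, seed=1)
        exact = draw_sum_null([(100, 10, 20)], mode="exact")
        assert abs(null.mean() - exact.mean()) < 0.15

    def test_quantile_conventions(self):
        null = draw_sum_null([(6803, 221, 65), (8336, 250, 73), (7882, 245, 89)], mode="exact")
        assert null.quantile(0.95) == 11  # largest value with CDF <= 0.95
        assert null.quantile(0.95, convention="upper") == 12
        # monotone in q
        qs = [null.quantile(q) for q in (0.1, 0.3, 0.5, 0.7, 0.9, 0.99)]
        assert qs == sorted(qs)

    def test_invalid_stratum_rejected(self):
        with pytest.raises(ValueError):
            draw_sum_null([(10, 11, 2)], mode="exact")
        with pytest.raises(ValueError):
            draw_sum_null([(10, 2, 11)], mode="exact")


class TestBinomialDirectionTest:
    def test_zero_successes_upper_tail_one(self):
        assert binomial_direction_test(0, 23) == 1.0

    def test_all_successes_single_term(self):
        assert binomial_direction_test(23, 23) == pytest.approx(0.25**23, rel=1e-12)

    def test_monotone_decreasing_in_k(self):
        ps = [binomial_direction_test(k, 23) for k in range(24)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_two_sided_matches_exact_convention(self):
        # the two-sided exact test (R binom.test convention)
        assert binomial_direction_test(12, 23, 0.25, "two-sided") == pytest.approx(
            0.005985, abs=5e-7
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_direction_test(5, 3)
        with pytest.raises(ValueError):
            binomial_direction_test(1, 2, p0=0.0)
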