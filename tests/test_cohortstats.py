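"""HWE, segregation, exact contingency, LD and growth-regression checks."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stuntscan import cohortstats as cs, simdata
from stuntscan.cohortstats import GenotypeCounts, TwoLocusHaplotypeCounts


class TestHwe:
    @pytest.mark.parametrize("q,expected", [
        (0.52, (0.2304, 0.4992, 0.2704)),
        (1.0, (0.0, 0.0, 1.0)),
        (0.13, (0.7569, 0.2262, 0.0169)),
    ])
    def test_closed_forms(self, q, expected):
        freqs = cs.hwe_genotype_freqs(q)
        assert freqs == pytest.approx(expected, abs=1e-12)

    @given(q=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_frequencies_sum_to_one(self, q):
        assert sum(cs.hwe_genotype_freqs(q)) == pytest.approx(1.0,
                                                              abs=1e-12)

    @pytest.mark.parametrize("q,n,expected_p", [
        (0.0, 10, 1.0),
        (1.0, 1, 0.0),
    ])
    def test_prob_no_homozygotes_edges(self, q, n, expected_p):
        p, _ = cs.prob_no_homozygotes(q, n)
        assert p == expected_p

    def test_prob_no_homozygotes_closed_form(self):
        p, expected_count = cs.prob_no_homozygotes(0.13, 824)
        assert p == pytest.approx((1 - 0.13 ** 2) ** 824, rel=1e-12)
        assert p == pytest.approx(8.0e-7, rel=0.01)
        assert expected_count == pytest.approx(824 * 0.0169, rel=1e-12)

    def test_prob_no_homozygotes_decreasing(self):
        ps = [cs.prob_no_homozygotes(q, 100)[0]
              for q in (0.01, 0.05, 0.1, 0.2)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        ps = [cs.prob_no_homozygotes(0.1, n)[0] for n in (10, 50, 200)]
        assert all(b < a for a, b in zip(ps, ps[1:]))


class TestSegregation:
    def test_cohort_counts_against_mendelian_ratio(self):
        """26:56:23 vs 1:2:1 — chi-square 0.638, p 0.727 (hand computed)."""
        res = cs.segregation_test((26, 56, 23), (1, 2, 1),
                                  method="pearson")
        assert res.statistic == pytest.approx(0.638095, abs=1e-5)
        assert res.p_value == pytest.approx(0.72684, abs=1e-4)
        g = cs.segregation_test((26, 56, 23), (1, 2, 1), method="g_test")
        assert g.p_value == pytest.approx(0.722, abs=5e-3)

    def test_exact_ratio_gives_p_one(self):
        res = cs.segregation_test((25, 50, 25), (1, 2, 1))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_multinomial_close_to_pearson(self):
        exact = cs.segregation_test((26, 56, 23), (1, 2, 1),
                                    method="exact_multinomial")
        pearson = cs.segregation_test((26, 56, 23), (1, 2, 1),
                                      method="pearson")
        assert abs(exact.p_value - pearson.p_value) < 0.02

    def test_zero_expected_class_rejected(self):
        with pytest.raises(ValueError, match="zero expected"):
            cs.segregation_test((5, 5, 5), (1, 1, 0))


def exhaustive_exact_p(table: np.ndarray) -> float:
    """Independent oracle: enumerate tables cell-wise and accumulate the
    multivariate hypergeometric pmf computed from factorials."""
    table = np.asarray(table)
    rows = table.sum(axis=1)
    k = int(table[:, 1].sum())

    def pmf(events):
        num = 0.0
        for r, a in zip(rows, events):
            num += (math.lgamma(r + 1) - math.lgamma(a + 1)
                    - math.lgamma(r - a + 1))
        n = int(rows.sum())
        num -= (math.lgamma(n + 1) - math.lgamma(k + 1)
                - math.lgamma(n - k + 1))
        return math.exp(num)

    p_obs = pmf(table[:, 1])
    total = 0.0
    ranges = [range(int(r) + 1) for r in rows[:-1]]
    for partial in itertools.product(*ranges):
        last = k - sum(partial)
        if 0 <= last <= rows[-1]:
            p = pmf(list(partial) + [last])
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


class TestGenotypeOutcomeExact:
    def test_cohort_mortality_association(self):
        """17 of 18 dead-or-culled calves homozygous mutant: p far below
        0.0005."""
        table = [[26, 0], [55, 1], [6, 17]]
        p = cs.genotype_outcome_exact_test(table)
        assert p < 0.0005

    def test_independent_table_p_one(self):
        p = cs.genotype_outcome_exact_test([[10, 5], [20, 10]])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_2x2(self):
        table = [[8, 2], [1, 5]]
        p = cs.genotype_outcome_exact_test(table)
        _, p_scipy = stats.fisher_exact(table)
        assert p == pytest.approx(p_scipy, rel=1e-9)

    def test_matches_exhaustive_enumeration_3x2(self, rng):
        for _ in range(20):
            rows = rng.integers(1, 8, size=3)
            events = [int(rng.integers(0, r + 1)) for r in rows]
            if sum(events) == 0 or sum(events) == sum(rows):
                continue
            table = np.array([[r - e, e] for r, e in zip(rows, events)])
            p = cs.genotype_outcome_exact_test(table)
            assert p == pytest.approx(exhaustive_exact_p(table), rel=1e-9)

    def test_row_permutation_symmetric(self):
        t = [[26, 0], [55, 1], [6, 17]]
        p1 = cs.genotype_outcome_exact_test(t)
        p2 = cs.genotype_outcome_exact_test(t[::-1])
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert 0 < p1 <= 1

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            cs.genotype_outcome_exact_test([[5, 0], [3, 0]])


class TestTwoLocusLd:
    def test_perfect_coupling(self):
        d, dp, r2 = cs.two_locus_ld(TwoLocusHaplotypeCounts(50, 0, 0, 50))
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independence(self):
        d, dp, r2 = cs.two_locus_ld(TwoLocusHaplotypeCounts(25, 25, 25, 25))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_indicator_correlation(self):
        h = TwoLocusHaplotypeCounts(49, 1, 0, 50)
        d, dp, r2 = cs.two_locus_ld(h)
        assert dp == pytest.approx(1.0)
        # direct correlation of allele indicator variables
        x = np.array([1] * 49 + [1] * 1 + [0] * 0 + [0] * 50)
        y = np.array([1] * 49 + [0] * 1 + [1] * 0 + [0] * 50)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-9)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            cs.two_locus_ld(TwoLocusHaplotypeCounts(50, 0, 50, 0))

    @given(counts=st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds(self, counts):
        h = TwoLocusHaplotypeCounts(*counts)
        try:
            d, dp, r2 = cs.two_locus_ld(h)
        except ValueError:
            return
        assert -1 - 1e-9 <= dp <= 1 + 1e-9
        assert 0 - 1e-9 <= r2 <= abs(dp) + 1e-9


class TestExpectedAffected:
    @pytest.mark.parametrize("q,sire,expected", [
        (0.13, "carrier", 0.065),
        (0.0, "carrier", 0.0),
        (0.13, "hom", 0.13),
    ])
    def test_closed_forms(self, q, sire, expected):
        assert cs.expected_affected_offspring(q, sire) == pytest.approx(
            expected, abs=1e-12)


class TestCarrierFreqComparison:
    def test_study_scale_counts(self):
        f1, f2, p = cs.carrier_freq_comparison(29, 86, 211, 829)
        assert f1 == pytest.approx(0.337, abs=1e-3)
        assert f2 == pytest.approx(0.255, abs=1e-3)
        assert 0.05 < p < 0.2  # not significant at the 5% level

    def test_identical_proportions(self):
        _, _, p = cs.carrier_freq_comparison(10, 40, 20, 80)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_hypergeometric_closed_form(self):
        k1, n1, k2, n2 = 3, 10, 9, 12
        _, _, p = cs.carrier_freq_comparison(k1, n1, k2, n2)
        _, p_scipy = stats.fisher_exact(
            [[k1, n1 - k1], [k2, n2 - k2]])
        assert p == pytest.approx(p_scipy, rel=1e-12)


GROUPING = {"AA": "unaffected", "AG": "unaffected", "GG": "affected"}


class TestGrowthRegression:
    def test_deficit_lowers_affected_slope(self):
        dosages = simdata.mendelian_carrier_cross_dosages(105, seed=4)
        cohort = simdata.simulate_cohort(dosages, simdata.OutcomeModel(),
                                         seed=4)
        res = cs.growth_group_regression(cohort, GROUPING,
                                         response="weight_kg",
                                         window=(180.0, 365.0))
        assert res.slopes["affected"] < res.slopes["unaffected"]

    def test_single_group_zero_slope_difference(self):
        dosages = [0] * 30
        cohort = simdata.simulate_cohort(dosages, simdata.OutcomeModel(),
                                         seed=5)
        res = cs.growth_group_regression(
            cohort, {"AA": "all", "AG": "all", "GG": "all"})
        assert res.groups == ("all",)
        assert res.interaction_p == 1.0

    def test_null_interaction_p_uniform(self):
        """With no genotype effect the interaction p-value is uniform
        across simulated cohorts (Kolmogorov-Smirnov check, 200 seeds)."""
        model = simdata.OutcomeModel(mortality_prob=0.0, deficit=0.0)
        pvals = []
        for seed in range(200):
            dosages = simdata.mendelian_carrier_cross_dosages(60, seed)
            cohort = simdata.simulate_cohort(dosages, model, seed=seed)
            res = cs.growth_group_regression(cohort, GROUPING,
                                             response="height_cm",
                                             window=(0.0, 365.0))
            pvals.append(res.interaction_p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_no_data_in_window_rejected(self):
        cohort = simdata.simulate_cohort([0, 2], simdata.OutcomeModel(),
                                         seed=6)
        with pytest.raises(ValueError):
            cs.growth_group_regression(cohort, GROUPING,
                                       window=(9000.0, 9999.0))
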