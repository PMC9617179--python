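"""Exact stratified tests, pooled estimates and multiplicity corrections."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import rvburden as rv
from rvburden.stats import StratifiedTable, cmh_null_distribution


def hypergeom_pmf(N, m1, n1):
    """Independent central-hypergeometric pmf via math.comb."""
    lo, hi = max(0, n1 + m1 - N), min(n1, m1)
    total = math.comb(N, n1)
    return lo, [math.comb(m1, k) * math.comb(N - m1, n1 - k) / total
                for k in range(lo, hi + 1)]


def doubled_tail_fisher(a, b, c, d):
    """Doubled smaller hypergeometric tail, the oracle for the one-stratum
    exact CMH reduction."""
    N, m1, n1 = a + b + c + d, a + c, a + b
    lo, pmf = hypergeom_pmf(N, m1, n1)
    p_le = sum(pmf[: a - lo + 1])
    p_ge = sum(pmf[a - lo:])
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMantelHaenszel:
    def test_symmetric_single_stratum_is_unity(self):
        or_, lo, hi = rv.mh_pooled_odds_ratio(StratifiedTable.single(10, 90, 10, 90))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_evaluated_two_strata(self):
        # (4,6,2,8) and (3,7,3,7), both n=20: MH = 2.65/1.65
        t = StratifiedTable(np.array([4, 3]), np.array([6, 7]),
                            np.array([2, 3]), np.array([8, 7]))
        or_, _, _ = rv.mh_pooled_odds_ratio(t)
        assert or_ == pytest.approx(2.65 / 1.65)

    def test_single_stratum_reduces_to_crude_or(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, size=4)
            or_, _, _ = rv.mh_pooled_odds_ratio(StratifiedTable.single(a, b, c, d))
            assert or_ == pytest.approx(a * d / (b * c))

    def test_zero_denominator_flags_infinite(self):
        or_, lo, hi = rv.mh_pooled_odds_ratio(StratifiedTable.single(5, 5, 0, 10))
        assert np.isinf(or_) and np.isnan(lo) and np.isnan(hi)


class TestExactCMH:
    def test_single_stratum_matches_doubled_tail_fisher(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            got = rv.cmh_exact_test(StratifiedTable.single(a, b, c, d)).p_two_sided
            assert got == pytest.approx(doubled_tail_fisher(a, b, c, d), abs=1e-12)

    def test_balanced_table_gives_p_one(self):
        assert rv.cmh_exact_test(StratifiedTable.single(5, 5, 5, 5)).p_two_sided == 1.0

    def test_two_symmetric_strata_by_brute_force_convolution(self):
        # each stratum (1,1,1,1): S ranges over {0,1,2} per stratum
        t = StratifiedTable(np.array([1, 1]), np.array([1, 1]),
                            np.array([1, 1]), np.array([1, 1]))
        res = rv.cmh_exact_test(t)
        # independent brute force over the 3x3 support
        _, pmf1 = hypergeom_pmf(4, 2, 2)
        dist = {}
        for s1, p1 in enumerate(pmf1):
            for s2, p2 in enumerate(pmf1):
                dist[s1 + s2] = dist.get(s1 + s2, 0.0) + p1 * p2
        s_obs = 2
        p_le = sum(v for k, v in dist.items() if k <= s_obs)
        p_ge = sum(v for k, v in dist.items() if k >= s_obs)
        assert res.p_two_sided == pytest.approx(min(1, 2 * min(p_le, p_ge)))
        assert res.p_two_sided == pytest.approx(1.0)

    def test_null_distribution_is_proper(self, rng):
        t = StratifiedTable(np.array([3, 2, 5]), np.array([7, 8, 5]),
                            np.array([10, 4, 6]), np.array([30, 16, 24]))
        _, dist = cmh_null_distribution(t)
        assert dist.sum() == pytest.approx(1.0)
        assert (dist >= 0).all()

    def test_empty_stratum_changes_nothing(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 15, size=4))
            base = StratifiedTable.single(a, b, c, d)
            padded = StratifiedTable(np.array([a, 0]), np.array([b, 0]),
                                     np.array([c, 0]), np.array([d, 0]))
            r1, r2 = rv.cmh_exact_test(base), rv.cmh_exact_test(padded)
            assert r1.p_two_sided == pytest.approx(r2.p_two_sided)
            assert r1.pooled_or == pytest.approx(r2.pooled_or)

    def test_all_degenerate_strata_return_p_one(self):
        res = rv.cmh_exact_test(StratifiedTable.single(0, 5, 0, 5))
        assert res.p_two_sided == 1.0 and res.degenerate

    def test_asymptotic_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import StratifiedTable as SmTable
        tables = [np.array([[12, 88], [25, 175]]), np.array([[8, 42], [10, 90]])]
        t = StratifiedTable(np.array([12, 8]), np.array([88, 42]),
                            np.array([25, 10]), np.array([175, 90]))
        ours = rv.cmh_asymptotic_test(t)
        sm = SmTable(np.stack([tb.T for tb in tables], axis=-1).astype(float))
        res = sm.test_null_odds(correction=False)
        assert ours.p_two_sided == pytest.approx(res.pvalue, rel=1e-8)


class TestFisher:
    def test_empty_carrier_margin_gives_one(self):
        assert rv.fisher_exact_test(0, 5, 0, 5).p_two_sided == 1.0

    def test_enumerated_small_table(self):
        # (2,3,1,4): every table in the support is no more probable than
        # the observed one, so the point-probability p is exactly 1
        res = rv.fisher_exact_test(2, 3, 1, 4)
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(2 * 4 / (3 * 1))

    def test_within_factor_two_of_doubled_tail(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            p_point = rv.fisher_exact_test(a, b, c, d).p_two_sided
            p_doubled = doubled_tail_fisher(a, b, c, d)
            assert p_point <= 2 * p_doubled + 1e-12
            assert p_doubled <= 2 * p_point + 1e-12

    def test_all_zero_table_degenerate(self):
        res = rv.fisher_exact_test(0, 0, 0, 0)
        assert res.p_two_sided == 1.0 and res.degenerate

    def test_ci_brackets_sample_or_on_regular_tables(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(3, 30, size=4))
            res = rv.fisher_exact_test(a, b, c, d)
            assert res.ci_low <= max(res.odds_ratio, res.ci_low)
            assert res.ci_low < res.ci_high


class TestInflationAndCorrections:
    def test_lambda_definition_points(self):
        assert rv.genomic_inflation_lambda([0.5] * 10) == pytest.approx(1.0)
        expected = sps.chi2.isf(0.01, 1) / sps.chi2.ppf(0.5, 1)
        assert rv.genomic_inflation_lambda([0.01] * 10) == pytest.approx(expected)
        assert expected == pytest.approx(14.59, abs=0.01)

    def test_lambda_near_one_under_uniform_null(self, rng):
        p = rng.uniform(size=10_000)
        assert rv.genomic_inflation_lambda(p) == pytest.approx(1.0, abs=0.05)

    def test_lambda_input_validation(self):
        with pytest.raises(ValueError):
            rv.genomic_inflation_lambda([])
        with pytest.raises(ValueError):
            rv.genomic_inflation_lambda([0.0, 0.5])

    def test_bonferroni(self):
        assert rv.bonferroni_alpha(0.05, 1860) == pytest.approx(2.7e-5, rel=0.005)
        assert rv.bonferroni_alpha(0.05, 1) == 0.05
        assert rv.bonferroni_alpha(0.05, 2) == 0.025
        with pytest.raises(ValueError):
            rv.bonferroni_alpha(0.05, 0)

    def test_bh_hand_example_and_identity(self):
        assert rv.bh_adjust([0.2])[0] == pytest.approx(0.2)
        adj = rv.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_properties_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            adj = rv.bh_adjust(p)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rv.bh_adjust([0.5, 1.5])
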