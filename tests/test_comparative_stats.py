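"""Unit and property tests for the 2x2, rank and sample-size statistics."""
import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import trialcea as tc
from trialcea.comparative_stats import DegenerateTableError


def table(a, b, c, d):
    return tc.ContingencyTable2x2(a, b, c, d)


def fisher_two_sided_enumeration(t):
    """Independent oracle: sum of all margin-fixed table probabilities <= observed."""
    n = t.n
    r1, c1 = t.a + t.b, t.a + t.c
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = prob(t.a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(p for p in (prob(x) for x in range(lo, hi + 1)) if p <= p_obs * (1 + 1e-9))


def mann_whitney_u_brute(x, y):
    return sum(
        1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
    )


class TestPearsonChi2:
    def test_trial_cure_rate_statistic(self):
        r = tc.pearson_chi2(table(46, 20, 58, 6))
        assert round(r.statistic, 3) == 8.894
        assert r.df == 1
        assert round(r.p_value, 3) == 0.003

    def test_no_association(self):
        r = tc.pearson_chi2(table(10, 10, 10, 10))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_matches_scipy_contingency(self):
        # independent route: scipy's chi2_contingency without correction
        t = table(4, 62, 21, 43)
        r = tc.pearson_chi2(t)
        chi2, p, df, _ = sps.chi2_contingency(t.counts, correction=False)
        assert r.statistic == pytest.approx(chi2, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            tc.pearson_chi2(table(0, 0, 5, 5))

    @given(
        st.tuples(*[st.integers(1, 60)] * 4)
    )
    def test_invariant_under_row_and_column_swap(self, counts):
        a, b, c, d = counts
        r1 = tc.pearson_chi2(table(a, b, c, d))
        r2 = tc.pearson_chi2(table(d, c, b, a))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)


class TestFisherExact:
    def test_perfect_separation(self):
        # p is the two-tail hypergeometric sum, clipped at 1
        r = tc.fisher_exact(table(0, 10, 10, 0))
        expected = min(1.0, fisher_two_sided_enumeration(table(0, 10, 10, 0)))
        assert r.p_value == pytest.approx(expected, rel=1e-9)

    def test_balanced_table(self):
        assert tc.fisher_exact(table(5, 5, 5, 5)).p_value == pytest.approx(1.0)

    def test_perianal_haematoma_row_significant(self):
        r = tc.fisher_exact(table(6, 60, 0, 64))
        assert r.p_value < 0.05
        assert r.p_value == pytest.approx(
            fisher_two_sided_enumeration(table(6, 60, 0, 64)), rel=1e-9
        )

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_enumeration_on_small_tables(self, counts):
        a, b, c, d = counts
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        r = tc.fisher_exact(table(a, b, c, d))
        assert 0 < r.p_value <= 1
        assert r.p_value == pytest.approx(
            min(1.0, fisher_two_sided_enumeration(table(a, b, c, d))), rel=1e-9
        )


class TestOddsRatio:
    @pytest.mark.parametrize(
        "events, expected_or, expected_ci",
        [
            ((4, 66, 21, 64), 7.57, (2.43, 23.62)),
            ((20, 66, 17, 64), 0.83, (0.39, 1.79)),
            ((36, 66, 24, 64), 0.50, (0.25, 1.01)),
            ((40, 66, 40, 64), 1.08, (0.53, 2.20)),
        ],
    )
    def test_trial_complication_odds_ratios(self, events, expected_or, expected_ci):
        e1, n1, e2, n2 = events
        r = tc.odds_ratio(tc.ContingencyTable2x2.from_events(e1, n1, e2, n2))
        assert round(r.or_point, 2) == expected_or
        assert round(r.ci_low, 2) == pytest.approx(expected_ci[0], abs=0.011)
        assert round(r.ci_high, 2) == pytest.approx(expected_ci[1], abs=0.011)
        assert not r.continuity_corrected

    def test_identical_arms_give_unit_or(self):
        r = tc.odds_ratio(table(12, 30, 12, 30))
        assert r.or_point == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    def test_zero_cell_haldane_flagged(self):
        r = tc.odds_ratio(table(6, 60, 0, 64))
        assert r.continuity_corrected
        assert r.or_point > 0

    def test_double_diagonal_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            tc.odds_ratio(table(0, 10, 5, 0))

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_row_swap_reciprocal(self, counts):
        a, b, c, d = counts
        r1 = tc.odds_ratio(table(a, b, c, d))
        r2 = tc.odds_ratio(table(c, d, a, b))
        assert r1.or_point == pytest.approx(1.0 / r2.or_point, rel=1e-12)


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0] * 5
        r = tc.mann_whitney(x, list(x))
        assert r.statistic == pytest.approx(len(x) ** 2 / 2)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 8, size=14).astype(float)
        y = rng.integers(0, 8, size=17).astype(float)
        r = tc.mann_whitney(x, y)
        assert r.statistic == pytest.approx(mann_whitney_u_brute(x, y))

    def test_complete_separation_exact(self):
        r = tc.mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.statistic == 0.0
        # exhaustive: 2/C(6,3) orderings are at least this extreme two-sided
        assert r.p_value == pytest.approx(2 / comb(6, 3), rel=1e-9)
        assert "exact" in r.method

    def test_u_sum_identity_tie_free(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=23), rng.normal(size=31)
        ux = tc.mann_whitney(x, y).statistic
        uy = tc.mann_whitney(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            tc.mann_whitney([], [1.0])

    def test_type_i_error_rate(self):
        # 1000 null replicates at n=40/arm: rejection rate ~ alpha
        rng = np.random.default_rng(2024)
        rejections = sum(
            tc.mann_whitney(rng.normal(size=40), rng.normal(size=40)).p_value < 0.05
            for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rejections / 1000 - 0.05) < 3.5 * se


class TestTwoSampleT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        r = tc.two_sample_t(x, list(x))
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_summary_matches_raw(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(10, 2, 30), rng.normal(11, 3, 25)
        raw = tc.two_sample_t(x, y)
        summ = tc.two_sample_t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-9)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-9)

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        pooled = tc.two_sample_t(x, y, variant="pooled")
        welch = tc.two_sample_t(x, y, variant="welch")
        assert pooled.statistic != welch.statistic

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(77)
        rejections = sum(
            tc.two_sample_t(rng.normal(size=50), rng.normal(size=50)).p_value < 0.05
            for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rejections / 1000 - 0.05) < 3.5 * se


class TestEquivalenceSampleSize:
    def test_monotone_in_margin_and_power(self):
        base = tc.EquivalenceDesign(delta=0.23)
        wider = tc.EquivalenceDesign(delta=0.46)
        weaker = tc.EquivalenceDesign(delta=0.23, power=0.45)
        n = tc.equivalence_sample_size(base)
        assert tc.equivalence_sample_size(wider) < n
        assert tc.equivalence_sample_size(weaker) < n

    def test_invalid_margin_rejected(self):
        with pytest.raises(ValueError):
            tc.EquivalenceDesign(delta=0.0)

    def test_simulation_validates_returned_n(self):
        design = tc.EquivalenceDesign(delta=0.23, alpha=0.05, power=0.90)
        n = tc.equivalence_sample_size(design)
        coverage = tc.equivalence_coverage_simulation(n, design, n_trials=4000, seed=20)
        mc_se = np.sqrt(design.power * (1 - design.power) / 4000)
        assert coverage >= design.power - 2 * mc_se
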