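import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polytdm._rounding import round_half_up
from polytdm.trial_stats import (
    SurvivalDatum,
    TwoByTwo,
    chi_square_test,
    cox_hr,
    empirical_power,
    fisher_exact,
    km_estimate,
    logrank_test,
    relative_risk,
    risk_difference_newcombe,
    risk_difference_wald,
    sample_size_two_proportions,
    wilson_ci,
)

counts = st.integers(min_value=1, max_value=200)


@st.composite
def tables(draw):
    n_a = draw(st.integers(min_value=2, max_value=300))
    n_b = draw(st.integers(min_value=2, max_value=300))
    e_a = draw(st.integers(min_value=1, max_value=n_a - 1))
    e_b = draw(st.integers(min_value=1, max_value=n_b - 1))
    return TwoByTwo(e_a, n_a, e_b, n_b)


class TestRelativeRisk:
    def test_printed_response_row(self):
        est = relative_risk(TwoByTwo(95, 152, 95, 159))
        assert round_half_up(est.point, 3) == 1.046
        assert round_half_up(est.ci_low, 3) == 0.876
        assert round_half_up(est.ci_high, 3) == 1.249

    def test_printed_above_window_row(self):
        est = relative_risk(TwoByTwo(15, 127, 4, 131))
        assert round_half_up(est.point, 3) == 3.868
        assert round_half_up(est.ci_low, 3) == 1.319
        assert round_half_up(est.ci_high, 3) == 11.340

    def test_equal_proportions_give_unity(self):
        est = relative_risk(TwoByTwo(30, 100, 30, 100))
        assert est.point == pytest.approx(1.0)

    def test_zero_reference_events_raise(self):
        with pytest.raises(ZeroDivisionError):
            relative_risk(TwoByTwo(5, 10, 0, 10))

    def test_zero_exposed_events_flagged_without_interval(self):
        est = relative_risk(TwoByTwo(0, 10, 5, 10))
        assert est.point == 0.0
        assert est.ci_low is None and "zero_cell" in est.method

    @given(tables())
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, t):
        assert relative_risk(t).point * relative_risk(t.swapped()).point == pytest.approx(1.0)


class TestRiskDifference:
    def test_printed_wald_row(self):
        est = risk_difference_wald(TwoByTwo(95, 152, 95, 159))
        assert round_half_up(100 * est.point, 2) == 2.75
        assert round_half_up(100 * est.ci_low, 2) == -8.08
        assert round_half_up(100 * est.ci_high, 2) == 13.58

    def test_printed_wald_mortality_point(self):
        est = risk_difference_wald(TwoByTwo(47, 152, 60, 159))
        assert round_half_up(100 * est.point, 2) == -6.81

    def test_identical_arms_symmetric(self):
        est = risk_difference_wald(TwoByTwo(40, 100, 40, 100))
        assert est.point == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_printed_newcombe_row(self):
        est = risk_difference_newcombe(TwoByTwo(81, 127, 51, 131))
        assert round_half_up(100 * est.point, 2) == 24.85
        assert round_half_up(100 * est.ci_high, 2) == 35.99
        # printed lower bound 12.68; small rounding divergence tolerated
        assert 100 * est.ci_low == pytest.approx(12.68, abs=0.02)

    def test_newcombe_bounds_stay_in_unit_interval_for_degenerate_arms(self):
        est = risk_difference_newcombe(TwoByTwo(10, 10, 0, 10))
        assert -1.0 <= est.ci_low <= est.ci_high <= 1.0

    def test_wilson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for events, n in ((81, 127), (51, 131), (3, 30), (0, 10), (10, 10)):
            lo, hi = wilson_ci(events, n)
            sm_lo, sm_hi = proportion_confint(events, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(sm_lo, abs=1e-10)
            assert hi == pytest.approx(sm_hi, abs=1e-10)

    @given(tables())
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_both_methods(self, t):
        for fn in (risk_difference_wald, risk_difference_newcombe):
            a = fn(t)
            b = fn(t.swapped())
            assert a.point == pytest.approx(-b.point)
            assert a.ci_low == pytest.approx(-b.ci_high, abs=1e-12)
            assert a.ci_high == pytest.approx(-b.ci_low, abs=1e-12)


class TestChiSquare:
    def test_printed_final_attainment_row(self):
        stat, p = chi_square_test(TwoByTwo(82, 127, 62, 131))
        assert stat == pytest.approx(7.77, abs=0.005)
        assert round_half_up(p, 3) == 0.005

    def test_hand_formula(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 82, 45, 62, 69
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = chi_square_test(TwoByTwo(82, 127, 62, 131))
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_without_correction(self):
        t = TwoByTwo(36, 152, 44, 159)
        stat, p = chi_square_test(t)
        res = sps.chi2_contingency(
            [[t.events_a, t.n_a - t.events_a], [t.events_b, t.n_b - t.events_b]],
            correction=False,
        )
        assert stat == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue)

    def test_balanced_table_is_null(self):
        stat, p = chi_square_test(TwoByTwo(25, 50, 25, 50))
        assert stat == 0.0
        assert p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test(TwoByTwo(0, 10, 0, 10))

    @given(tables())
    @settings(max_examples=50, deadline=None)
    def test_invariance_to_swaps(self, t):
        stat, _ = chi_square_test(t)
        assert chi_square_test(t.swapped())[0] == pytest.approx(stat)
        flipped = TwoByTwo(t.n_a - t.events_a, t.n_a, t.n_b - t.events_b, t.n_b)
        assert chi_square_test(flipped)[0] == pytest.approx(stat)


def brute_force_fisher(t: TwoByTwo) -> float:
    """Exhaustive two-sided hypergeometric p over tables with fixed margins."""
    m = t.events_a + t.events_b
    total = t.n_a + t.n_b
    p_obs = sps.hypergeom.pmf(t.events_a, total, m, t.n_a)
    p = 0.0
    for x in range(max(0, m - t.n_b), min(m, t.n_a) + 1):
        px = sps.hypergeom.pmf(x, total, m, t.n_a)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(TwoByTwo(5, 10, 5, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [TwoByTwo(0, 10, 10, 10), TwoByTwo(3, 12, 7, 9)])
    def test_matches_brute_force_enumeration(self, t):
        assert fisher_exact(t) == pytest.approx(brute_force_fisher(t), rel=1e-9)

    def test_agrees_with_chi_square_asymptotically(self):
        t = TwoByTwo(5100, 10_000, 4900, 10_000)
        assert fisher_exact(t) == pytest.approx(chi_square_test(t)[1], abs=0.01)


class TestSurvival:
    def test_km_no_censoring_equals_empirical_survivor(self):
        data = [SurvivalDatum(t, True, "HD") for t in (1.0, 2.0, 3.0, 4.0)]
        curve = km_estimate(data)["HD"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[4.0] == pytest.approx(0.0)

    def test_km_single_subject(self):
        curve = km_estimate([SurvivalDatum(5.0, True, "HD")])["HD"]
        assert curve["survival"].iloc[0] == 1.0
        assert curve.loc[curve["time"] == 5.0, "survival"].iloc[0] == 0.0

    def test_km_hand_computed_with_interleaved_censoring(self):
        # times 1, 2+, 3, 4, 5+, 6 -> S = 5/6, 0.625, 0.41667, then 0 at 6
        spec = [(1, True), (2, False), (3, True), (4, True), (5, False), (6, True)]
        data = [SurvivalDatum(float(t), e, "HD") for t, e in spec]
        curve = km_estimate(data)["HD"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[3.0] == pytest.approx(0.625)
        assert surv[4.0] == pytest.approx(5 / 12)
        assert surv[6.0] == pytest.approx(0.0)

    def test_logrank_identical_arms_is_null(self):
        base = [(1.0, True), (2.0, False), (3.0, True)]
        data = [SurvivalDatum(t, e, arm) for arm in ("HD", "LD") for t, e in base]
        stat, p = logrank_test(data)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_matches_hand_oracle(self):
        # independent O-E / variance computation on an 8-subject example
        spec = [
            (1.0, True, "HD"), (3.0, True, "HD"), (5.0, False, "HD"), (8.0, True, "HD"),
            (2.0, True, "LD"), (4.0, True, "LD"), (6.0, True, "LD"), (9.0, False, "LD"),
        ]
        data = [SurvivalDatum(t, e, a) for t, e, a in spec]

        def oracle(records):
            times = sorted({t for t, e, _ in records if e})
            o_minus_e = 0.0
            var = 0.0
            for t in times:
                at_risk = [(tt, ee, aa) for tt, ee, aa in records if tt >= t]
                n = len(at_risk)
                n1 = sum(1 for _, _, a in at_risk if a == "HD")
                d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
                d1 = sum(1 for tt, ee, a in at_risk if tt == t and ee and a == "HD")
                o_minus_e += d1 - d * n1 / n
                if n > 1:
                    var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
            return o_minus_e**2 / var

        stat, p = logrank_test(data)
        assert stat == pytest.approx(oracle(spec), rel=1e-9)
        assert p == pytest.approx(sps.chi2.sf(oracle(spec), 1), rel=1e-9)

    def test_single_arm_rejected(self):
        data = [SurvivalDatum(1.0, True, "HD"), SurvivalDatum(2.0, True, "HD")]
        with pytest.raises(ValueError):
            logrank_test(data)

    def test_cox_recovers_simulated_rate_ratio(self):
        rng = np.random.default_rng(2024)
        true_hr = 0.6
        data = [
            SurvivalDatum(float(t), True, "HD")
            for t in rng.exponential(1.0 / (0.01 * true_hr), size=250)
        ] + [
            SurvivalDatum(float(t), True, "LD")
            for t in rng.exponential(1.0 / 0.01, size=250)
        ]
        est = cox_hr(data, ref_arm="LD")
        assert est.ci_low < true_hr < est.ci_high
        assert est.point == pytest.approx(true_hr, rel=0.25)


class TestSampleSizeAndPower:
    def test_printed_design_total(self):
        n = sample_size_two_proportions(0.58, 1.26, 0.05, 0.80)
        assert 309 <= n <= 312  # paper printed 311

    def test_power_monotonicity(self):
        n_low = sample_size_two_proportions(0.58, 1.26, 0.05, 0.80)
        n_high = sample_size_two_proportions(0.58, 1.26, 0.05, 0.999)
        assert n_high > n_low

    def test_invalid_treatment_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.8, 1.3)

    def test_null_calibration(self):
        rej = empirical_power(152, 159, 0.58, 0.58, 0.05, 10_000, rng_seed=11)
        assert rej == pytest.approx(0.05, abs=0.015)

    def test_power_at_design_alternative(self):
        power = empirical_power(152, 159, 0.58 * 1.26, 0.58, 0.05, 10_000, rng_seed=11)
        assert power >= 0.80

    def test_matches_analytic_power(self):
        p1, p2, n1, n2 = 0.7308, 0.58, 152, 159
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        delta = p1 - p2
        se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        analytic = sps.norm.sf((1.959964 * se0 - delta) / se1)
        mc = empirical_power(n1, n2, p1, p2, 0.05, 10_000, rng_seed=3)
        assert mc == pytest.approx(analytic, abs=0.02)

    def test_closed_form_n_achieves_target_power(self):
        total = sample_size_two_proportions(0.58, 1.26, 0.05, 0.80)
        per_arm = total // 2
        mc = empirical_power(per_arm, total - per_arm, 0.7308, 0.58, 0.05, 10_000, rng_seed=5)
        assert mc >= 0.79  # Monte-Carlo margin around the 0.80 target
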