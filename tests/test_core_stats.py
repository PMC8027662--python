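"""Closed-form statistics: frozen examples and algebraic properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrselect import (
    AssocSummary,
    SelectionDesign,
    chisq_upper_p,
    conditional_test,
    fisher_z,
    fisher_z_signed,
    min_test,
    p_to_chisq_threshold,
    smr_statistic,
    steiger_test,
    wald_chisq,
    wald_ratio,
    wald_to_min_abs_corr,
)

GW_CUTOFF = 29.71679

positive_wald = st.floats(1e-6, 1e4)


class TestWaldChisq:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [(0.0, 1.0, 0.0), (-3.0, 1.5, 4.0), (3.0, 1.5, 4.0), (math.sqrt(13), 1.0, 13.0)],
    )
    def test_examples(self, beta, se, expected):
        assert wald_chisq(beta, se) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_chisq(1.0, 0.0)
        with pytest.raises(ValueError):
            wald_chisq(1.0, -0.1)


class TestThresholdConversions:
    def test_genome_wide_cutoff(self):
        assert p_to_chisq_threshold(5e-8) == pytest.approx(GW_CUTOFF, abs=5e-6)

    def test_upper_p_at_printed_cutoff(self):
        # the printed cutoff carries 7 significant figures
        assert chisq_upper_p(GW_CUTOFF) == pytest.approx(5e-8, rel=1e-5)

    def test_trivial_endpoints(self):
        assert chisq_upper_p(0.0) == 1.0
        assert p_to_chisq_threshold(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_cutoff_against_normal_oracle(self):
        # 1-df chi-square upper quantile = squared two-sided normal quantile
        oracle = stats.norm.isf(0.025) ** 2
        assert p_to_chisq_threshold(0.05) == pytest.approx(oracle, rel=1e-12)
        assert chisq_upper_p(3.8415) == pytest.approx(
            2 * stats.norm.sf(math.sqrt(3.8415)), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            p_to_chisq_threshold(bad)

    @given(st.floats(1e-12, 1.0, exclude_min=False))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, p):
        assert chisq_upper_p(p_to_chisq_threshold(p)) == pytest.approx(p, rel=1e-9)

    def test_negative_wald_rejected(self):
        with pytest.raises(ValueError):
            chisq_upper_p(-0.5)


class TestCorrelationFloors:
    @pytest.mark.parametrize(
        "n, expected",
        [(100, 0.4823663), (1000, 0.1700451), (10000, 0.05443772)],
    )
    def test_printed_floors(self, n, expected):
        assert wald_to_min_abs_corr(GW_CUTOFF, n) == pytest.approx(expected, rel=1e-6)

    def test_strictly_decreasing_in_n(self):
        floors = [wald_to_min_abs_corr(GW_CUTOFF, n) for n in (50, 100, 500, 5000, 50000)]
        assert all(a > b for a, b in zip(floors, floors[1:]))

    def test_inverts_corr_to_wald(self):
        # |rho| = 1/sqrt(1+(n-2)/W)  <=>  W = (n-2) rho^2/(1-rho^2)
        n, w = 1000, 17.3
        rho = wald_to_min_abs_corr(w, n)
        assert (n - 2) * rho**2 / (1 - rho**2) == pytest.approx(w, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wald_to_min_abs_corr(GW_CUTOFF, 2)


class TestFisherZ:
    @pytest.mark.parametrize(
        "rho, expected",
        [(0.1700451, 0.17171315), (0.05443772, 0.05449159), (0.0, 0.0)],
    )
    def test_printed_values(self, rho, expected):
        assert fisher_z(rho) == pytest.approx(expected, abs=5e-8)

    def test_absolute_value_convention(self):
        assert fisher_z(-0.3) == fisher_z(0.3) > 0

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_signed_variant_is_odd(self, rho):
        assert fisher_z_signed(-rho) == pytest.approx(-fisher_z_signed(rho), abs=1e-12)

    def test_monotone_in_abs_rho(self):
        grid = np.linspace(0, 0.99, 50)
        vals = [fisher_z(r) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestWaldRatio:
    def test_examples(self):
        assert wald_ratio(0.0, 2.5) == 0.0
        assert wald_ratio(1.7, 1.7) == 1.0

    @given(st.floats(-10, 10), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, b_gy, b_gx):
        assert wald_ratio(-b_gy, b_gx) == pytest.approx(-wald_ratio(b_gy, b_gx))
        assert wald_ratio(b_gy, -b_gx) == pytest.approx(-wald_ratio(b_gy, b_gx))

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError, match="weak-instrument"):
            wald_ratio(1.0, 0.0)


class TestSMRStatistic:
    def test_equal_walds_give_half(self):
        t, _ = smr_statistic(GW_CUTOFF, GW_CUTOFF)
        assert t == pytest.approx(GW_CUTOFF / 2)
        assert t == pytest.approx(14.858395, rel=1e-6)

    def test_limit_at_infinite_partner(self):
        t, _ = smr_statistic(GW_CUTOFF, 1e12)
        assert t == pytest.approx(GW_CUTOFF, rel=1e-6)

    def test_both_zero_total(self):
        assert smr_statistic(0.0, 0.0) == (0.0, 1.0)

    @given(positive_wald, positive_wald)
    @settings(max_examples=100, deadline=None)
    def test_dominance(self, a, b):
        t, _ = smr_statistic(a, b)
        assert t < min(a, b)

    @given(positive_wald, positive_wald)
    @settings(max_examples=100, deadline=None)
    def test_half_harmonic_mean(self, a, b):
        t, _ = smr_statistic(a, b)
        assert t == pytest.approx(0.5 * (2 * a * b / (a + b)), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            smr_statistic(-1.0, 2.0)


class TestMinTest:
    def test_statistic_and_p(self):
        t, p = min_test(30.0, 40.0)
        assert t == 30.0
        assert p == pytest.approx(chisq_upper_p(30.0))

    def test_zero_partner_never_significant(self):
        _, p = min_test(0.0, 50.0)
        assert p == 1.0

    @given(positive_wald, positive_wald, st.floats(1e-6, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_rejects_iff_both_marginals_reject(self, a, b, alpha):
        _, p = min_test(a, b)
        both = chisq_upper_p(a) < alpha and chisq_upper_p(b) < alpha
        assert (p < alpha) == both


class TestConditionalTest:
    def test_bonferroni_threshold(self):
        _, threshold, _ = conditional_test(1.0, 9639, 0.05)
        assert threshold == pytest.approx(5.18726e-6, rel=1e-6)

    def test_zero_statistic_never_rejects(self):
        p, _, reject = conditional_test(0.0, 10, 0.05)
        assert p == 1.0 and not reject

    def test_boundary_is_strict(self):
        # p exactly at the threshold does not reject
        w = p_to_chisq_threshold(5e-8)
        p, threshold, reject = conditional_test(w, 1, 5e-8)
        assert p == pytest.approx(threshold, rel=1e-12)
        assert not reject

    def test_domain_error(self):
        with pytest.raises(ValueError):
            conditional_test(1.0, 0, 0.05)


@given(positive_wald, positive_wald, st.floats(1e-5, 0.2))
@settings(max_examples=150, deadline=None)
def test_nested_rejection_sets(w_gx, w_gy, alpha):
    """Rejecting with SMR implies rejecting with the min-test implies
    rejecting with the conditional test, at any shared level."""
    _, p_smr = smr_statistic(w_gx, w_gy)
    _, p_min = min_test(w_gx, w_gy)
    p_cond, _, _ = conditional_test(w_gy, 1, alpha)
    assert p_smr >= p_min >= p_cond


class TestSteigerTest:
    def test_symmetric_inputs_undetermined(self):
        res = steiger_test(0.2, 0.2, 500, 500)
        assert res.t_steiger == 0.0
        assert res.direction == "undetermined"

    def test_frozen_arithmetic(self):
        # direct evaluation of the displayed statistic at the retained-column
        # means of the rho=0.15 selection experiment
        res = steiger_test(
            math.tanh(0.1903508), math.tanh(0.1512602), 1000, 10000
        )
        assert res.t_steiger == pytest.approx(1.1770, abs=2e-4)
        assert res.direction == "undetermined"

    def test_antisymmetric_under_swap(self):
        a = steiger_test(0.4, 0.1, 800, 2000)
        b = steiger_test(0.1, 0.4, 2000, 800)
        assert a.t_steiger == pytest.approx(-b.t_steiger)

    def test_directions(self):
        assert steiger_test(0.5, 0.05, 1000, 1000).direction == "x_to_y"
        assert steiger_test(0.05, 0.5, 1000, 1000).direction == "y_to_x"

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            steiger_test(0.1, 0.1, 3, 100)


class TestSelectionDesign:
    def test_derived_cutoffs(self):
        design = SelectionDesign(5e-8)
        assert design.w_threshold == pytest.approx(GW_CUTOFF, abs=5e-6)
        assert design.fisher_z_cutoff(1000) == pytest.approx(0.17171315, abs=5e-8)
        assert design.fisher_z_cutoff(10000) == pytest.approx(0.05449159, abs=5e-8)

    def test_fisher_z_cutoff_is_transform_of_floor(self):
        design = SelectionDesign(1e-5)
        for n in (100, 1000):
            assert design.fisher_z_cutoff(n) == pytest.approx(
                fisher_z(design.min_abs_corr(n))
            )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            SelectionDesign(0.0)


class TestAssocSummary:
    def test_wald_and_consistency(self):
        rec = AssocSummary("rs1", 0.5, 0.1, p=float(chisq_upper_p(25.0)), n=1000)
        assert rec.wald == pytest.approx(25.0)

    def test_inconsistent_p_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            AssocSummary("rs1", 0.5, 0.1, p=0.5, n=1000)

    def test_invalid_fields(self):
        with pytest.raises(ValueError):
            AssocSummary("rs1", 0.5, 0.0)
        with pytest.raises(ValueError):
            AssocSummary("rs1", 0.5, 0.1, n=3)
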