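"""Closed-form model predictions and derived turnover/partition/discrimination."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isoturn import (
    GrowthCurve,
    IsotopeValue,
    ModelDParams,
    ModelGParams,
    WeightRatio,
    convert_turnover_scale,
    discrimination_factor,
    growth_rate_k,
    partition_turnover,
    predict_model_d,
    predict_model_g,
    turnover_days,
    turnover_weight_fold,
)
from isoturn.core import ImplausibleIsotopeWarning
from isoturn.reference import MEAN_DRY_WEIGHT_MG


class TestIsotopeValue:
    def test_plausible_value_passes_silently(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            IsotopeValue(-16.3, "d13C")

    def test_implausible_value_flagged_not_rejected(self):
        with pytest.warns(ImplausibleIsotopeWarning):
            v = IsotopeValue(25.0, "d13C")
        assert v.value == 25.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            IsotopeValue(bad, "d15N")


class TestPredictModelG:
    def test_equilibrium_limit(self):
        p = ModelGParams(delta_eq=-16.3, a=-4.4, c=-1.474)
        assert predict_model_g(p, 1e9) == pytest.approx(-16.3, abs=1e-6)

    def test_pure_dilution_halves_offset_at_doubled_weight(self):
        p = ModelGParams(delta_eq=0.0, a=1.0, c=-1.0)
        assert predict_model_g(p, 2.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        # hand calculation: 1.6**-1.474 = 0.50018, so -16.3 - 4.4*0.50018 = -18.50
        p = ModelGParams(delta_eq=-16.3, a=-4.4, c=-1.474)
        assert predict_model_g(p, 1.6) == pytest.approx(-16.3 - 4.4 * 1.6**-1.474, abs=1e-12)
        assert predict_model_g(p, 1.6) == pytest.approx(-18.50, abs=0.01)

    def test_nonpositive_weight_ratio_rejected(self):
        p = ModelGParams(delta_eq=0.0, a=1.0, c=-1.0)
        with pytest.raises(ValueError):
            predict_model_g(p, 0.0)

    @given(w_r=st.floats(1.0, 1e3))
    def test_dilution_model_equivalence(self, w_r):
        """For c = -1 the power law is exactly delta_eq + a / w_r."""
        p = ModelGParams(delta_eq=-16.0, a=-4.0, c=-1.0)
        assert predict_model_g(p, w_r) == pytest.approx(-16.0 - 4.0 / w_r, rel=1e-12)


class TestPredictModelD:
    def test_initial_value_at_switch(self):
        p = ModelDParams(delta_eq=14.2, a=7.1 - 14.2, m=0.041, k=0.062)
        assert predict_model_d(p, 0.0) == pytest.approx(7.1)

    def test_one_half_life(self):
        p = ModelDParams(delta_eq=0.0, a=8.0, m=math.log(2), k=0.0)
        assert predict_model_d(p, 1.0) == pytest.approx(4.0)

    def test_offset_halves_at_d50(self):
        p = ModelDParams(delta_eq=-15.6, a=-3.0, m=0.035, k=0.0694)
        assert predict_model_d(p, 6.64) == pytest.approx(-17.10, abs=0.005)

    def test_pre_switch_time_rejected(self):
        p = ModelDParams(delta_eq=0.0, a=1.0, m=0.1, k=0.0)
        with pytest.raises(ValueError):
            predict_model_d(p, -1.0)

    @given(m=st.floats(0.001, 0.5), k=st.floats(0.0, 0.5))
    def test_half_life_halves_offset_exactly(self, m, k):
        p = ModelDParams(delta_eq=5.0, a=-4.0, m=m, k=k)
        d50 = turnover_days(m, k, 50)
        assert predict_model_d(p, d50) - p.delta_eq == pytest.approx(p.a / 2, rel=1e-9)


class TestGrowthRate:
    @pytest.mark.parametrize(
        "w_i, w_t, t, expected",
        [
            (0.80, 22.78, 54, 0.0620),  # A6: ln(28.475)/54
            (2.20, 65.85, 49, 0.0694),  # A11: ln(29.93)/49
            (5.0, 5.0, 10, 0.0),
        ],
    )
    def test_endpoint_growth_rates(self, w_i, w_t, t, expected):
        assert growth_rate_k(w_i, w_t, t) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("w_i, w_t, t", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_invalid_inputs_rejected(self, w_i, w_t, t):
        with pytest.raises(ValueError):
            growth_rate_k(w_i, w_t, t)


class TestTurnover:
    @pytest.mark.parametrize(
        "c, alpha, expected",
        [(-1.474, 50, 1.6), (-1.0, 50, 2.0), (-0.844, 95, 34.8)],
    )
    def test_weight_fold_milestones(self, c, alpha, expected):
        assert turnover_weight_fold(c, alpha) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "m, k, alpha, expected",
        [(0.035, 0.0694, 50, 6.6), (0.0, math.log(2), 50, 1.0), (0.040, 0.0620, 95, 29.4)],
    )
    def test_chronological_milestones(self, m, k, alpha, expected):
        assert turnover_days(m, k, alpha) == pytest.approx(expected, abs=0.05)

    def test_invalid_rate_or_alpha_rejected(self):
        with pytest.raises(ValueError):
            turnover_weight_fold(0.5, 50)
        with pytest.raises(ValueError):
            turnover_weight_fold(-1.0, 100)
        with pytest.raises(ValueError):
            turnover_days(-0.1, 0.05, 50)

    @given(m=st.floats(0.001, 1.0), k=st.floats(0.0, 0.5))
    def test_equilibrium_to_half_life_ratio_is_universal(self, m, k):
        """D95/D50 = ln(0.05)/ln(0.5) ~ 4.32: equilibrium after 4-5 half-lives."""
        ratio = turnover_days(m, k, 95) / turnover_days(m, k, 50)
        assert ratio == pytest.approx(math.log(0.05) / math.log(0.5), rel=1e-12)

    @given(c=st.floats(-8.0, -0.05))
    def test_weight_fold_decreases_with_stronger_metabolism(self, c):
        """More negative c (more metabolic turnover) means less growth needed."""
        g = turnover_weight_fold(c, 50)
        g_stronger = turnover_weight_fold(c - 0.5, 50)
        assert g_stronger < g
        assert turnover_weight_fold(c, 95) > g


class TestPartition:
    @pytest.mark.parametrize(
        "g50, p_m_expected",
        [(1.6, 0.25), (2.0, 0.0), (2.5, 0.0)],  # 2.5: raw negative, clipped
    )
    def test_metabolic_fraction(self, g50, p_m_expected):
        p_g, p_m = partition_turnover(g50)
        assert p_m == pytest.approx(p_m_expected, abs=0.001)
        assert p_g + p_m == pytest.approx(1.0)

    def test_g50_below_one_rejected(self):
        with pytest.raises(ValueError):
            partition_turnover(0.9)

    @given(g50=st.floats(1.0, 50.0))
    def test_fractions_sum_to_one_and_match_complement(self, g50):
        p_g, p_m = partition_turnover(g50)
        assert 0 <= p_m <= 1
        assert p_g == pytest.approx(1 - p_m, rel=1e-12)


class TestDiscrimination:
    @pytest.mark.parametrize(
        "delta_eq, delta_diet, expected",
        [(-16.3, -18.03, 1.7), (5.0, 5.0, 0.0), (14.6, 12.27, 2.3)],
    )
    def test_difference_from_diet(self, delta_eq, delta_diet, expected):
        res = discrimination_factor(delta_eq, delta_diet, isotope="d15N")
        assert res.delta_delta == pytest.approx(expected, abs=0.05)

    def test_isotope_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            discrimination_factor(IsotopeValue(-16.3, "d13C"), IsotopeValue(12.3, "d15N"))

    @given(x=st.floats(-30, 20), y=st.floats(-30, 20))
    def test_antisymmetry(self, x, y):
        fwd = discrimination_factor(x, y, isotope="d13C").delta_delta
        rev = discrimination_factor(y, x, isotope="d13C").delta_delta
        assert fwd == pytest.approx(-rev)


class TestWeightRatioType:
    def test_ratio_field(self):
        wr = WeightRatio(w_i=0.80, w_t=22.78)
        assert wr.w_r == pytest.approx(28.475)

    def test_positive_weights_required(self):
        with pytest.raises(ValueError):
            WeightRatio(w_i=0.0, w_t=1.0)


class TestScaleConversion:
    def test_exponential_curve_closed_form(self):
        curve = GrowthCurve.exponential(w0=0.80, k=0.0620, switch_day=6, final_day=60)
        days = convert_turnover_scale(curve, 1.6, "weight->days")
        assert days == pytest.approx(math.log(1.6) / 0.0620, rel=1e-9)
        assert days == pytest.approx(7.6, abs=0.05)

    def test_switch_point_maps_to_zero(self):
        curve = GrowthCurve.exponential(w0=2.2, k=0.07, switch_day=11, final_day=60)
        assert convert_turnover_scale(curve, 1.0, "weight->days") == pytest.approx(0.0)
        assert convert_turnover_scale(curve, 0.0, "days->weight") == pytest.approx(1.0)

    def test_round_trip_on_observed_weights(self):
        w = MEAN_DRY_WEIGHT_MG["A11"]
        days = np.array(sorted(w), float)
        curve = GrowthCurve(days, np.array([w[int(d)] for d in days]), switch_day=11)
        for fold in (1.5, 3.0, 10.0, 25.0):
            d = curve.weight_fold_to_days(fold)
            assert curve.days_to_weight_fold(d) == pytest.approx(fold, rel=1e-6)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GrowthCurve([], [], switch_day=6)

    def test_extrapolation_flagged(self):
        curve = GrowthCurve([6, 11, 18], [0.8, 1.3, 3.3], switch_day=6)
        with pytest.warns(UserWarning, match="extrapolat"):
            curve.weight_fold_to_days(50.0)
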