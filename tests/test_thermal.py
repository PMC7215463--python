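"""Thermal-index formulas: wet-bulb, WBGT, PMV heat balance, PT, daily maxima."""

import math
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from heatrisk import (
    InvalidInputError,
    MetRecord,
    NumericalFailureError,
    OutOfBranchError,
    ReferencePerson,
    compute_pmv,
    daily_max,
    estimate_mrt,
    kma_wbgt,
    pmv_scale_factor,
    pt_from_pmv,
    reference_wbgt,
    stull_wet_bulb,
)
from heatrisk.thermal import thermal_load


class TestStullWetBulb:
    @pytest.mark.parametrize(
        "ta, rh, expected, tol",
        [
            (20.0, 50.0, 13.7, 0.05),
            # RH -> 0+ limit at Ta=0: atan(1.67633) - 4.686035
            (0.0, 1e-12, math.atan(1.67633) - 4.686035, 1e-6),
        ],
    )
    def test_known_values(self, ta, rh, expected, tol):
        assert stull_wet_bulb(ta, rh) == pytest.approx(expected, abs=tol)

    def test_saturation_wet_bulb_close_to_dry_bulb(self):
        # at 100% RH the wet-bulb equals the dry-bulb up to fit error
        assert abs(stull_wet_bulb(30.0, 100.0) - 30.0) < 1.0

    @given(
        ta=st.floats(0.0, 40.0),
        rh=st.floats(5.0, 100.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_never_far_above_dry_bulb(self, ta, rh):
        assert stull_wet_bulb(ta, rh) <= ta + 1.0

    @pytest.mark.parametrize("ta, rh", [(20.0, 0.0), (20.0, -5.0), (float("nan"), 50.0)])
    def test_invalid_inputs(self, ta, rh):
        with pytest.raises(InvalidInputError):
            stull_wet_bulb(ta, rh)


class TestWbgt:
    @pytest.mark.parametrize(
        "tw, ta, expected",
        [
            (0.0, 0.0, -0.2442),  # intercept
            (25.0, 25.0, 25.3518),
            (10.0, 30.0, 19.5702),
        ],
    )
    def test_kma_polynomial(self, tw, ta, expected):
        assert kma_wbgt(tw, ta) == pytest.approx(expected, abs=1e-10)

    def test_bit_stable(self):
        assert kma_wbgt(17.3, 29.1) == kma_wbgt(17.3, 29.1)

    def test_reference_identity_and_example(self):
        for t in (-10.0, 0.0, 25.0, 40.0):
            assert reference_wbgt(t, t, t) == pytest.approx(t, abs=1e-12)
        assert reference_wbgt(30.0, 40.0, 35.0) == pytest.approx(32.5, abs=1e-12)

    def test_reference_weights_recovered_by_least_squares(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(10, 40, size=(50, 3))
        y = np.array([reference_wbgt(*row) for row in X])
        coef, *_ = np.linalg.lstsq(np.c_[X, np.ones(50)], y, rcond=None)
        assert coef[:3] == pytest.approx([0.7, 0.2, 0.1], abs=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            kma_wbgt(float("inf"), 20.0)
        with pytest.raises(InvalidInputError):
            reference_wbgt(20.0, float("nan"), 20.0)


class TestPmvScaleFactor:
    def test_at_rest_and_asymptote(self):
        assert pmv_scale_factor(0.0) == pytest.approx(0.3305, abs=1e-12)
        assert pmv_scale_factor(2000.0) == pytest.approx(0.0275, abs=1e-6)

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 500, 100)
        values = [pmv_scale_factor(m) for m in grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert min(values) > 0.0275

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            pmv_scale_factor(-1.0)


def _met(ta, rh=50.0, wind=0.0, tmrt=None, hour=15):
    return MetRecord(datetime(2018, 7, 20, hour), ta=ta, rh=rh, wind=wind, tmrt=tmrt)


class TestPmv:
    def test_pmv_is_scaled_thermal_load(self):
        person = ReferencePerson()
        met = _met(32.0, rh=60.0, wind=1.0)
        terms = thermal_load(32.0, 32.0, 60.0, met.wind + person.walking_speed, person)
        assert compute_pmv(met, person) == pytest.approx(
            pmv_scale_factor(person.metabolic_rate) * terms.Lth
        )

    def test_zero_thermal_load_gives_zero_pmv(self):
        # find the air temperature where the heat balance closes; PMV must vanish there
        person = ReferencePerson()
        f = lambda ta: compute_pmv(_met(ta, rh=50.0, wind=0.5), person)
        ta0 = brentq(f, 0.0, 35.0, xtol=1e-10)
        assert abs(f(ta0)) < 1e-8

    @pytest.mark.parametrize("base_ta", [22.0, 26.0, 30.0, 34.0])
    def test_monotone_in_air_temperature(self, base_ta):
        person = ReferencePerson()
        low = compute_pmv(_met(base_ta, rh=50.0, wind=1.0), person)
        high = compute_pmv(_met(base_ta + 5.0, rh=50.0, wind=1.0), person)
        assert high > low

    def test_monotone_in_radiant_temperature(self):
        person = ReferencePerson()
        pmvs = [
            compute_pmv(_met(30.0, rh=50.0, wind=1.0, tmrt=tr), person)
            for tr in (25.0, 30.0, 40.0, 55.0)
        ]
        assert all(a < b for a, b in zip(pmvs, pmvs[1:]))

    @pytest.mark.parametrize(
        "ta, tr, vel, rh, expected",
        [
            # sedentary comfort-standard validation points (1.2 met, 0.5 clo)
            (22.0, 22.0, 0.10, 60.0, -0.75),
            (27.0, 27.0, 0.10, 60.0, 0.77),
        ],
    )
    def test_comfort_standard_reference_points(self, ta, tr, vel, rh, expected):
        person = ReferencePerson(
            metabolic_rate=69.6, clothing_clo=0.5, walking_speed=0.0
        )
        pmv = compute_pmv(_met(ta, rh=rh, wind=vel, tmrt=tr), person)
        assert pmv == pytest.approx(expected, abs=0.15)

    def test_independent_clothing_temperature_solver(self):
        """The damped iteration agrees with a root-bracketing solve of the
        clothing-surface energy balance (an independent numerical path)."""
        person = ReferencePerson()
        ta, tr, rh, var = 33.0, 40.0, 55.0, 2.0
        terms = thermal_load(ta, tr, rh, var, person)

        icl = 0.155 * person.clothing_clo
        fcl = 1.05 + 0.645 * icl
        mw = person.metabolic_rate - person.external_work
        hcf = 12.1 * math.sqrt(var)

        def residual(tcl):
            hcn = 2.38 * abs(tcl - ta) ** 0.25
            hc = max(hcf, hcn)
            lhs = 35.7 - 0.028 * mw - icl * (
                3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
                + fcl * hc * (tcl - ta)
            )
            return lhs - tcl

        tcl = brentq(residual, ta - 20.0, ta + 30.0, xtol=1e-10)
        hcn = 2.38 * abs(tcl - ta) ** 0.25
        hc = max(hcf, hcn)
        r_skin = 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
        c_skin = fcl * hc * (tcl - ta)
        assert terms.Rskin == pytest.approx(r_skin, abs=0.05)
        assert terms.Cskin == pytest.approx(c_skin, abs=0.05)


class TestPtTranslation:
    def test_intercept_and_unit_slope_point(self):
        assert pt_from_pmv(0.0) == pytest.approx(16.83, abs=1e-12)
        assert pt_from_pmv(1.0) == pytest.approx(23.01, abs=1e-12)

    def test_slope_by_finite_difference(self):
        h = 1e-6
        slope = (pt_from_pmv(1.0 + h) - pt_from_pmv(1.0 - h)) / (2 * h)
        assert slope == pytest.approx(6.18, rel=1e-9)

    def test_cold_branch_rejected(self):
        with pytest.raises(OutOfBranchError):
            pt_from_pmv(-0.5)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing(self, a, b):
        if a + 1e-9 < b:  # separation beyond float rounding of the affine map
            assert pt_from_pmv(a) < pt_from_pmv(b)


class TestEstimateMrt:
    def test_explicit_tmrt_passthrough(self):
        met = _met(30.0, tmrt=45.0)
        assert estimate_mrt(met, lat=37.5) == 45.0

    def test_night_falls_back_to_air_temperature(self):
        met = MetRecord(datetime(2018, 7, 20, 2), ta=24.0, rh=70.0, cloud_amount=0.0)
        assert estimate_mrt(met, lat=37.5) == 24.0

    def test_full_overcast_falls_back(self):
        met = MetRecord(datetime(2018, 7, 20, 12), ta=28.0, rh=60.0, cloud_amount=1.0)
        assert estimate_mrt(met, lat=37.5) == pytest.approx(28.0)

    def test_clear_summer_noon_exceeds_air_temperature(self):
        met = MetRecord(datetime(2018, 7, 20, 12), ta=30.0, rh=50.0, cloud_amount=0.0)
        assert estimate_mrt(met, lat=37.5) > 30.0

    def test_missing_cloud_warns_and_falls_back(self, caplog):
        met = MetRecord(datetime(2018, 7, 20, 12), ta=30.0, rh=50.0)
        with caplog.at_level("WARNING"):
            assert estimate_mrt(met, lat=37.5) == 30.0
        assert any("cloud" in rec.message for rec in caplog.records)


class TestDailyMax:
    @staticmethod
    def _hours(day, values):
        return [datetime(2018, 7, day, h) for h in range(len(values))], list(values)

    def test_full_day_maximum(self):
        values = list(np.linspace(20, 31.2, 16)) + list(np.linspace(31, 22, 8))
        ts, vals = self._hours(1, values)
        series = daily_max(ts, vals)
        assert len(series) == 1
        assert series.values[0] == pytest.approx(31.2)

    def test_sparse_day_marked_missing(self):
        ts, vals = self._hours(1, [25.0] * 10)  # 10 < 18 valid hours
        series = daily_max(ts, vals)
        assert np.isnan(series.values[0])

    def test_order_invariance(self):
        ts1, v1 = self._hours(1, np.linspace(20, 30, 24))
        ts2, v2 = self._hours(2, np.linspace(21, 33, 24))
        ordered = daily_max(ts1 + ts2, v1 + v2)
        interleaved_ts = [t for pair in zip(ts1, ts2) for t in pair]
        interleaved_v = [v for pair in zip(v1, v2) for v in pair]
        shuffled = daily_max(interleaved_ts, interleaved_v)
        np.testing.assert_array_equal(ordered.values, shuffled.values)
        assert ordered.dates == shuffled.dates

    def test_length_equals_day_span(self):
        ts1, v1 = self._hours(1, [25.0] * 24)
        ts3, v3 = self._hours(3, [26.0] * 24)
        series = daily_max(ts1 + ts3, v1 + v3)
        assert len(series) == 3  # day 2 present as missing
        assert np.isnan(series.values[1])

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            daily_max([], [])


class TestMetRecordValidation:
    def test_rh_bounds(self):
        with pytest.raises(InvalidInputError):
            MetRecord(datetime(2018, 7, 1, 0), ta=20.0, rh=130.0)

    def test_dew_point_cannot_exceed_air_temperature(self):
        with pytest.raises(InvalidInputError):
            MetRecord(datetime(2018, 7, 1, 0), ta=20.0, rh=50.0, td=25.0)

    def test_negative_wind_rejected(self):
        with pytest.raises(InvalidInputError):
            MetRecord(datetime(2018, 7, 1, 0), ta=20.0, rh=50.0, wind=-1.0)
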