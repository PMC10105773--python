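import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limnoch4.constants import P_STANDARD, R_GAS, schmidt_ch4
from limnoch4.gas import (
    GasConditions,
    HeadspaceSample,
    K600Model,
    equilibrium_concentration,
    headspace_backcalc,
    henry_cp_ch4,
    k600_evaluate,
    k600_to_kgas,
    kgas_to_k600,
    wg_equilibrium_nmol,
)


class TestSolubility:
    def test_equilibrium_zero_partial_pressure(self):
        cond = GasConditions(t_w=15.0, x_ch4_atm=0.0)
        # pch4 = 0 -> c_eq = 0 (H_cp itself stays finite)
        assert equilibrium_concentration(cond) == 0.0

    def test_linearity_in_partial_pressure(self):
        c1 = equilibrium_concentration(GasConditions(t_w=15.0, x_ch4_atm=1.9e-6))
        c2 = equilibrium_concentration(GasConditions(t_w=15.0, x_ch4_atm=3.8e-6))
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_cold_water_holds_more(self):
        c_cold = equilibrium_concentration(GasConditions(t_w=5.0))
        c_warm = equilibrium_concentration(GasConditions(t_w=25.0))
        assert c_cold > c_warm

    def test_magnitude_against_published_range(self):
        # air-equilibrium CH4 in fresh water at ~1.9 ppm, 20-25 degC is ~2-3 nM
        c = wg_equilibrium_nmol(25.0)
        assert 2.0 < c < 3.5

    @given(st.floats(min_value=0.5, max_value=34.5))
    @settings(deadline=None, max_examples=40)
    def test_strictly_decreasing_in_temperature(self, t):
        assert henry_cp_ch4(t) > henry_cp_ch4(t + 5.0)

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            GasConditions(t_w=45.0)


class TestHeadspace:
    def test_ambient_equilibrated_water_returns_equilibrium(self):
        t_w = 20.0
        p = P_STANDARD
        x_amb = 1.9
        c_eq = float(henry_cp_ch4(t_w)) * x_amb * 1e-6 * p * 1e3
        s = HeadspaceSample(x_meas_ppm=x_amb, t_equil_c=t_w, x_amb_ppm=x_amb, p_atm=p)
        assert headspace_backcalc(s) == pytest.approx(c_eq, rel=1e-9)

    def test_small_headspace_limit(self):
        # V_air -> 0: measured gas is in equilibrium with the unchanged water
        t_w = 20.0
        x = 500.0
        s = HeadspaceSample(
            x_meas_ppm=x, t_equil_c=t_w, x_amb_ppm=0.0, v_air_ml=1e-6, v_water_ml=500.0
        )
        expect = float(henry_cp_ch4(t_w)) * x * 1e-6 * P_STANDARD * 1e3
        assert headspace_backcalc(s) == pytest.approx(expect, rel=1e-6)

    def test_round_trip_partitioning(self):
        # distribute a known C_w over both phases by Henry's law, back-calculate
        t_w, t_a, p = 18.0, 293.15, P_STANDARD
        c_w_true = 5.0  # mmol m-3
        v = 500e-6  # m3, each phase
        x_amb = 1.9e-6
        h_cp = float(henry_cp_ch4(t_w))
        n_total = c_w_true * 1e-3 * v + x_amb * p * v / (R_GAS * t_a)
        x_eq = n_total / (p * (h_cp * v + v / (R_GAS * t_a)))
        s = HeadspaceSample(
            x_meas_ppm=x_eq * 1e6, t_equil_c=t_w, x_amb_ppm=x_amb * 1e6, p_atm=p, t_a=t_a
        )
        assert headspace_backcalc(s) == pytest.approx(c_w_true, rel=1e-6)

    def test_negative_clipped_with_warning(self):
        s = HeadspaceSample(x_meas_ppm=0.5, t_equil_c=20.0, x_amb_ppm=5.0)
        with pytest.warns(UserWarning):
            assert headspace_backcalc(s) == 0.0

    def test_bad_volumes_rejected(self):
        with pytest.raises(ValueError):
            HeadspaceSample(x_meas_ppm=2.0, t_equil_c=20.0, v_air_ml=0.0)


class TestK600:
    @pytest.mark.parametrize(
        "name, u10, expected",
        [
            ("CC98", 0.0, 2.07),
            ("CC98", 1.0, 2.285),
            ("MA10-NB", 0.0, 2.0),
            ("MA10-MB", 2.0, 2.25 * 2 + 0.16),
            ("MA10-PB", 0.0, 0.0),  # -0.15 clipped to the physical floor
        ],
    )
    def test_table_values(self, name, u10, expected):
        assert k600_evaluate(K600Model(name, u10=u10)) == pytest.approx(expected)

    def test_vp13_uses_log_area(self):
        k10 = k600_evaluate(K600Model("VP13", u10=2.0, area_km2=10.0))
        k1 = k600_evaluate(K600Model("VP13", u10=2.0, area_km2=1.0))
        assert k10 - k1 == pytest.approx(0.39 * 2.0)

    def test_chamber_mean_passthrough(self):
        assert k600_evaluate(K600Model("chamber-mean", k600_chamber=4.2)) == 4.2

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            K600Model("XX99")


class TestSchmidtScaling:
    def test_sc600_is_identity_after_unit_conversion(self):
        assert k600_to_kgas(1.0, 600.0, 1.0) == pytest.approx(0.24)

    def test_half_exponent_above_wind_threshold(self):
        assert k600_to_kgas(4.1666667, 150.0, 5.0) == pytest.approx(2.0, rel=1e-6)

    def test_exponent_switch_at_threshold(self):
        sc = 300.0
        below = k600_to_kgas(1.0, sc, 3.69)
        above = k600_to_kgas(1.0, sc, 3.71)
        assert below / above == pytest.approx((600.0 / sc) ** (2.0 / 3.0 - 0.5), rel=1e-9)

    @given(st.floats(min_value=0.01, max_value=50.0))
    @settings(deadline=None, max_examples=30)
    def test_homogeneous_degree_one(self, k600):
        assert k600_to_kgas(k600, 450.0, 2.0) == pytest.approx(
            k600 * k600_to_kgas(1.0, 450.0, 2.0), rel=1e-12
        )

    def test_round_trip_inversion(self):
        k = k600_to_kgas(3.7, 820.0, 1.0)
        assert kgas_to_k600(k, 820.0, 1.0) == pytest.approx(3.7, rel=1e-12)


def test_schmidt_number_decreasing():
    t = np.linspace(0, 30, 40)
    assert np.all(np.diff(schmidt_ch4(t)) < 0)
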