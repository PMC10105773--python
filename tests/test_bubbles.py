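import numpy as np
import pytest
from scipy.integrate import solve_ivp

from limnoch4.bubbles import (
    BubbleSpec,
    EbullitionField,
    GASES,
    SedimentColumn,
    WaterColumn,
    feb_needed,
    rdis_profile,
    rise_and_dissolve,
    sediment_ebullition,
)


def column(depth=12.0):
    z = np.linspace(0.0, depth, 25)
    return WaterColumn(
        depth_m=z,
        temp_c=np.full_like(z, 10.0),
        conc_mmol_m3={
            "CH4": np.full_like(z, 1.0),
            "O2": np.full_like(z, 300.0),
            "N2": np.full_like(z, 600.0),
        },
    )


class TestRiseAndDissolve:
    def test_surface_release_is_identity(self):
        wc = column()
        res = rise_and_dissolve(BubbleSpec(release_depth_m=0.0), wc, sml_base_m=3.0)
        assert res.r_sml_umol == 0.0
        for g in GASES:
            assert res.surfacing_mol[g] == pytest.approx(res.initial_mol[g])

    @pytest.mark.parametrize("depth", [1.0, 5.0, 10.0])
    def test_mass_conservation(self, depth):
        wc = column()
        res = rise_and_dissolve(BubbleSpec(release_depth_m=depth), wc, sml_base_m=3.0)
        for g in GASES:
            total = res.dissolved_mol[g].sum() + res.surfacing_mol[g]
            assert total == pytest.approx(res.initial_mol[g], rel=5e-3, abs=1e-15)

    def test_grid_convergence(self):
        wc = column()
        b = BubbleSpec(release_depth_m=10.0)
        coarse = rise_and_dissolve(b, wc, sml_base_m=3.0, dz=0.05)
        fine = rise_and_dissolve(b, wc, sml_base_m=3.0, dz=0.005)
        assert coarse.r_sml_umol == pytest.approx(fine.r_sml_umol, rel=0.01)

    def test_tiny_bubble_fully_dissolves(self):
        wc = column(depth=25.0)
        b = BubbleSpec(release_depth_m=25.0, diameter_m=5e-4)
        res = rise_and_dissolve(b, wc, sml_base_m=5.0)
        assert res.fully_dissolved
        for g in ("CH4", "N2"):
            assert res.dissolved_mol[g].sum() == pytest.approx(res.initial_mol[g], rel=1e-9)

    def test_release_outside_column(self):
        with pytest.raises(ValueError):
            rise_and_dissolve(BubbleSpec(release_depth_m=50.0), column(), 3.0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            BubbleSpec(release_depth_m=5.0, fractions={"CH4": 0.7, "N2": 0.2})


class TestRdisProfile:
    def field(self, **kw):
        base = dict(
            bin_depth_m=[8.0], f_eb_swi=[0.01], delta_a_sed=[100.0],
            r_umol=[1.0], n0_umol=[1.0],
        )
        base.update(kw)
        return EbullitionField(**base)

    def test_zero_ebullition(self):
        f = self.field(f_eb_swi=[0.0])
        assert rdis_profile(f, 2.0, 1000.0) == 0.0

    def test_single_bin_arithmetic(self):
        # number flux = 0.01 mmol * 1e3 / 1 umol = 10 bubbles m-2 d-1
        assert rdis_profile(self.field(), 2.0, 1000.0) == pytest.approx(1.0)

    def test_two_bins_additive(self):
        f2 = self.field(
            bin_depth_m=[8.0, 6.0], f_eb_swi=[0.01, 0.02], delta_a_sed=[100.0, 50.0],
            r_umol=[1.0, 0.5], n0_umol=[1.0, 1.0],
        )
        single_a = rdis_profile(self.field(), 2.0, 1000.0)
        single_b = rdis_profile(
            self.field(bin_depth_m=[6.0], f_eb_swi=[0.02], delta_a_sed=[50.0], r_umol=[0.5]),
            2.0, 1000.0,
        )
        assert rdis_profile(f2, 2.0, 1000.0) == pytest.approx(single_a + single_b)

    def test_only_bins_below_depth_counted(self):
        assert rdis_profile(self.field(), 9.0, 1000.0) == 0.0

    def test_zero_area_error(self):
        with pytest.raises(ValueError):
            rdis_profile(self.field(), 2.0, 0.0)


class TestSedimentEbullition:
    def test_zero_production_zero_ebullition(self):
        col = SedimentColumn(c_top={"CH4": 0.001, "N2": 0.6})
        sol = sediment_ebullition(col, 0.0)
        assert sol.no_ebullition
        assert np.all(sol.e_rate == 0.0)
        assert sol.f_eb_swi == 0.0

    def test_low_production_all_diffusive(self):
        col = SedimentColumn(water_depth_m=10.0, c_top={"CH4": 0.001, "N2": 0.6})
        sol = sediment_ebullition(col, 0.05)
        assert sol.no_ebullition
        prod = np.trapezoid(col.production(sol.w0, "CH4"), col.z) * 1e3
        assert sol.f_diff_swi == pytest.approx(prod, rel=0.01)
        assert sol.f_diff_swi == pytest.approx(0.05, rel=1e-4)

    def test_high_production_partitions_and_closes(self):
        col = SedimentColumn(water_depth_m=3.0, c_top={"CH4": 0.001, "N2": 0.6})
        sol = sediment_ebullition(col, 8.3)
        assert not sol.no_ebullition
        assert sol.f_diff_swi == pytest.approx(8.3, rel=1e-4)
        assert sol.f_eb_swi > 0.0
        prod = np.trapezoid(col.production(sol.w0, "CH4"), col.z) * 1e3
        assert prod == pytest.approx(sol.f_diff_swi + sol.f_eb_swi, rel=0.01)

    def test_no_ebullition_above_surface_layer(self):
        col = SedimentColumn(water_depth_m=3.0, c_top={"CH4": 0.001, "N2": 0.6})
        sol = sediment_ebullition(col, 8.3)
        assert np.all(sol.e_rate[col.z <= col.z_eb_min] == 0.0)

    def test_finite_difference_matches_shooting_oracle(self):
        # unsaturated single-gas toy column: independent shooting-method solve
        col = SedimentColumn(
            water_depth_m=30.0, c_top={"CH4": 0.5, "N2": 0.0}, gases=("CH4",)
        )
        sol = sediment_ebullition(col, 0.2)
        assert sol.no_ebullition
        phi_d = col.porosity * col.diffusivity_m2_d("CH4")
        w0 = sol.w0

        def rhs(z, y):
            return [y[1], -w0 * np.exp(-z / col.lambda_m) / phi_d]

        def bottom_slope(s0):
            out = solve_ivp(rhs, (0, col.depth_max_m), [col.c_top["CH4"], s0],
                            rtol=1e-10, atol=1e-12)
            return out.y[1, -1]

        from scipy.optimize import brentq

        s_lo, s_hi = 0.0, 1e5
        s0 = brentq(bottom_slope, s_lo, s_hi, xtol=1e-10)
        out = solve_ivp(rhs, (0, col.depth_max_m), [col.c_top["CH4"], s0],
                        t_eval=col.z, rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.conc["CH4"], out.y[0], rtol=0.01, atol=1e-6)


class TestFebNeeded:
    def test_arithmetic(self):
        assert feb_needed(100.0, 1e4, 0.1, 1e3) == pytest.approx(10.0)

    def test_zero_pnet(self):
        assert feb_needed(0.0, 1e4, 0.1, 1e3) == 0.0

    def test_inverse_in_beta(self):
        assert feb_needed(100.0, 1e4, 0.2, 1e3) == pytest.approx(
            feb_needed(100.0, 1e4, 0.1, 1e3) / 2.0
        )

    def test_zero_beta_error(self):
        with pytest.raises(ValueError):
            feb_needed(100.0, 1e4, 0.0, 1e3)
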