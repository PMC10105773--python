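import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limnoch4.balance import (
    FluxSet,
    MonteCarloConfig,
    SOURCE_NAMES,
    Uncertain,
    budget_sources,
    fs_needed,
    fs_needed_mc,
    gamma_draws,
    k600_sensitivity_suite,
    kh_peeters,
    monte_carlo_fullscale,
    pnet_error_propagation,
    pnet_fullscale,
    source_contributions,
    upscaling_regression,
)
from limnoch4.geometry import LakeMorphometry


def simple_morph(a_a=1000.0, a_s=300.0, a_z=700.0, v=1000.0):
    return LakeMorphometry(a_surface=a_a, a_sediment=a_s, a_sml_base=a_z, v_sml=v)


def fluxset(f_s=0.0, f_a=0.0, f_z=0.0, r_dis=0.0, **kw):
    return FluxSet(
        f_s=Uncertain(*f_s) if isinstance(f_s, tuple) else Uncertain(f_s),
        f_a=Uncertain(*f_a) if isinstance(f_a, tuple) else Uncertain(f_a),
        f_z=Uncertain(*f_z) if isinstance(f_z, tuple) else Uncertain(f_z),
        r_dis=Uncertain(*r_dis) if isinstance(r_dis, tuple) else Uncertain(r_dis),
        **kw,
    )


class TestFullScale:
    def test_all_zero(self):
        assert pnet_fullscale(simple_morph(), fluxset()) == 0.0

    def test_atmospheric_term_only(self):
        # A_a F_a = 10^4 mmol d-1, V = 1000 m3 -> 10^4 umol m-3 d-1
        p = pnet_fullscale(simple_morph(), fluxset(f_a=10.0))
        assert p == pytest.approx(1e4)

    def test_budget_closure(self):
        morph = simple_morph()
        fx = fluxset(f_s=4.0, f_a=3.0, f_z=0.5, r_dis=30.0)
        p = pnet_fullscale(morph, fx)
        # re-insert into the steady balance: residual vanishes
        lhs = (
            morph.a_sediment * fx.f_s.mean
            - morph.a_surface * fx.f_a.mean
            + morph.a_sml_base * fx.f_z.mean
            + fx.r_dis.mean * 1e-3 * morph.v_sml
            + p * 1e-3 * morph.v_sml
        )
        biggest = morph.a_surface * fx.f_a.mean
        assert abs(lhs) < 1e-9 * biggest

    def test_sediment_flux_reduces_pnet(self):
        p0 = pnet_fullscale(simple_morph(), fluxset(f_a=3.0))
        p1 = pnet_fullscale(simple_morph(), fluxset(f_a=3.0, f_s=2.0))
        assert p1 < p0


class TestKhPeeters:
    def test_unit_length(self):
        k_si, _ = kh_peeters(1.0)
        assert k_si == pytest.approx(1.4e-4)

    def test_hundred_meters(self):
        _, k_d = kh_peeters(100.0)
        assert k_d == pytest.approx(1.67e3, rel=5e-3)

    def test_monotone(self):
        assert kh_peeters(200.0)[0] > kh_peeters(100.0)[0]


class TestMonteCarlo:
    def test_gamma_moment_matching(self):
        rng = np.random.default_rng(42)
        draws = gamma_draws(rng, Uncertain(8.3, 6.7), 100_000)
        assert np.all(draws >= 0.0)
        assert draws.mean() == pytest.approx(8.3, rel=0.02)
        assert draws.std(ddof=1) == pytest.approx(6.7, rel=0.02)
        # shape/scale from moment matching
        assert 8.3**2 / 6.7**2 == pytest.approx(1.535, abs=5e-3)
        assert 6.7**2 / 8.3 == pytest.approx(5.408, abs=5e-3)

    def test_degenerate_sds_collapse_to_point(self):
        morph = simple_morph()
        fx = fluxset(f_s=4.0, f_a=3.0, f_z=0.5, r_dis=30.0)
        est = monte_carlo_fullscale(morph, fx, MonteCarloConfig(n_iter=500, seed=1))
        assert est.sd == 0.0
        assert np.all(est.samples == est.point)

    def test_reproducible_with_seed(self):
        morph = simple_morph()
        fx = fluxset(f_s=(4.0, 2.0), f_a=(3.0, 1.0), f_z=(0.5, 0.3), r_dis=(30.0, 9.0))
        cfg = MonteCarloConfig(n_iter=2000, seed=7)
        a = monte_carlo_fullscale(morph, fx, cfg)
        b = monte_carlo_fullscale(morph, fx, cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_point_within_interquartile_range(self):
        morph = simple_morph()
        fx = fluxset(f_s=(4.0, 2.0), f_a=(3.0, 1.0), f_z=(0.5, 0.3), r_dis=(30.0, 9.0))
        est = monte_carlo_fullscale(morph, fx, MonteCarloConfig(n_iter=20_000, seed=3))
        q1, _, q3 = est.quartiles
        assert q1 <= est.point <= q3

    def test_convergence_of_summaries(self):
        morph = simple_morph()
        fx = fluxset(f_s=(4.0, 2.0), f_a=(3.0, 1.0), f_z=(0.5, 0.3))
        small = monte_carlo_fullscale(morph, fx, MonteCarloConfig(n_iter=10_000, seed=5))
        big = monte_carlo_fullscale(morph, fx, MonteCarloConfig(n_iter=20_000, seed=6))
        se = small.sd / np.sqrt(small.samples.size)
        assert abs(big.mean - small.mean) < 3.0 * se


class TestSourceContributions:
    def test_simple_split(self):
        assert np.allclose(source_contributions([2.0, 1.0, 1.0, 0.0]), [50, 25, 25, 0])

    def test_negative_zeroed(self):
        assert np.allclose(source_contributions([2.0, -1.0, 2.0, 0.0]), [50, 0, 50, 0])

    def test_single_source(self):
        assert np.allclose(source_contributions([0.0, 0.0, 3.0, 0.0]), [0, 0, 100, 0])

    def test_all_nonpositive_error(self):
        with pytest.raises(ValueError):
            source_contributions([-1.0, 0.0, -2.0, 0.0])

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=200)
    def test_sums_to_hundred_whenever_defined(self, sources):
        if max(sources) <= 0:
            return
        sc = source_contributions(sources)
        assert sc.sum() == pytest.approx(100.0, abs=0.1)
        assert np.all(sc >= 0.0)

    def test_budget_sources_units(self):
        morph = simple_morph()
        fx = fluxset(f_s=4.0, f_a=3.0, f_z=0.5, r_dis=30.0)
        src = budget_sources(morph, fx, 100.0)
        assert src["F_s"] == pytest.approx(4.0 * 300.0 * 1e-3)
        assert src["P_net"] == pytest.approx(100.0 * 1000.0 * 1e-6)
        assert set(src) == set(SOURCE_NAMES)


class TestErrorPropagation:
    def test_zero_error(self):
        err, _ = pnet_error_propagation(fluxset(f_a=3.0), simple_morph(), 100.0, 0.0)
        assert err == 0.0

    def test_linearity_with_stated_slope(self):
        morph = simple_morph()
        fx = fluxset(f_a=3.0)
        expected_slope = 3.0 * 1e-3 * morph.a_sediment / (100.0 * 1e-6 * morph.v_sml)
        for k_err in (-0.5, 0.2, 0.5):
            err, slope = pnet_error_propagation(fx, morph, 100.0, k_err)
            assert slope == pytest.approx(expected_slope)
            assert err == pytest.approx(expected_slope * k_err)

    def test_balanced_case_slope_one(self):
        # F_a * A_s == P_net * V_SML -> slope 1
        morph = simple_morph(a_s=500.0, v=1000.0)
        fx = fluxset(f_a=2.0)  # 2 mmol * 500 m2 = 1 mol d-1
        p_net = 1000.0  # umol m-3 d-1 * 1000 m3 = 1 mol d-1
        err, slope = pnet_error_propagation(fx, morph, p_net, 0.3)
        assert slope == pytest.approx(1.0)
        assert err == pytest.approx(0.3)

    def test_surface_area_switch(self):
        morph = simple_morph()
        _, s_sed = pnet_error_propagation(fluxset(f_a=3.0), morph, 100.0, 0.1)
        _, s_sur = pnet_error_propagation(
            fluxset(f_a=3.0), morph, 100.0, 0.1, atm_area="surface"
        )
        assert s_sur / s_sed == pytest.approx(morph.a_surface / morph.a_sediment)

    def test_zero_pnet_undefined(self):
        with pytest.raises(ValueError):
            pnet_error_propagation(fluxset(f_a=3.0), simple_morph(), 0.0, 0.1)


class TestFsNeeded:
    def test_atmospheric_only(self):
        morph = simple_morph()
        assert fs_needed(morph, fluxset(f_a=3.0)) == pytest.approx(3.0 * 1000.0 / 300.0)

    def test_consistency_when_budget_already_closed(self):
        morph = simple_morph()
        fx = fluxset(f_s=4.0, f_a=3.0, f_z=0.5, r_dis=30.0)
        # choose F_a so that P_net = 0 with the given F_s
        f_a_closed = (
            morph.a_sediment * 4.0 + morph.a_sml_base * 0.5 + 30.0 * 1e-3 * morph.v_sml
        ) / morph.a_surface
        fx2 = fluxset(f_s=4.0, f_a=f_a_closed, f_z=0.5, r_dis=30.0)
        assert pnet_fullscale(morph, fx2) == pytest.approx(0.0, abs=1e-9)
        assert fs_needed(morph, fx2) == pytest.approx(4.0)

    def test_decreasing_in_fz(self):
        morph = simple_morph()
        lo = fs_needed(morph, fluxset(f_a=3.0, f_z=1.0))
        hi = fs_needed(morph, fluxset(f_a=3.0, f_z=0.0))
        assert lo < hi

    def test_mc_variant_centers_on_point(self):
        morph = simple_morph()
        fx = fluxset(f_a=(3.0, 1.0), f_z=(0.5, 0.2), r_dis=(30.0, 5.0))
        draws = fs_needed_mc(morph, fx, MonteCarloConfig(n_iter=50_000, seed=2))
        assert np.mean(draws) == pytest.approx(fs_needed(morph, fx), rel=0.05)


class TestUpscaling:
    @staticmethod
    def records(n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for _ in range(n):
            chla, lc, z_s = rng.uniform(1, 9), rng.uniform(1, 8), rng.uniform(1, 10)
            x = chla * lc * z_s
            rate = 0.002 * x + 0.01 + rng.normal(0.0, noise)
            c = rng.uniform(0.5, 5.0)
            recs.append(dict(p_net=rate * c * 1e3, c_ch4=c, chla=chla, lc=lc, z_secchi=z_s))
        return recs

    def test_exact_line_gives_r2_one(self):
        fit = upscaling_regression(self.records())
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.002, rel=1e-6)

    def test_permuted_predictor_destroys_fit(self):
        recs = self.records(n=20, noise=0.0, seed=1)
        rng = np.random.default_rng(123)
        perm = rng.permutation(20)
        rates = [(r["p_net"], r["c_ch4"]) for r in recs]
        for i, j in enumerate(perm):
            recs[i]["p_net"], recs[i]["c_ch4"] = rates[j]
        fit = upscaling_regression(recs)
        assert fit.r2 < 0.2

    def test_common_rescaling_preserves_r2(self):
        recs = self.records(noise=0.005, seed=2)
        fit1 = upscaling_regression(recs)
        for r in recs:
            r["c_ch4"] *= 10.0
            r["p_net"] *= 10.0  # same specific rate under a unit change
        fit2 = upscaling_regression(recs)
        assert fit2.r2 == pytest.approx(fit1.r2, rel=1e-9)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-9)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            upscaling_regression(self.records(n=2))
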