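"""Synthetic lakes and synthetic raw measurements.

Every input the pipeline consumes can be generated here with known ground
truth attached, so each estimator is testable as a round trip: forward-model
plus instrument-grade noise in, recovered parameter out. Presets emulate the
two trophic regimes of small stratified pre-alpine lakes — eutrophic
(surface fluxes of a few mmol m-2 d-1, CH4-rich hypolimnion, detectable
ebullition) and oligotrophic (an order of magnitude lower fluxes, no
ebullition) — with flux magnitudes inside the observed field ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .balance import FluxSet, Uncertain, kh_peeters
from .benthic import BenthicIncubation, PorewaterProfile, transient_headspace_curve
from .constants import R_GAS
from .geometry import LakeMorphometry, RadialGeometry, TemperatureProfile, sml_volume_of_revolution
from .lateral import LateralInputs, Transect, lateral_steady_solve

PRESETS = {
    # ranges: (low, high) for uniform draws; cv = SD/mean for the flux SDs
    "eutrophic": dict(
        f_a=(1.5, 5.0), f_s=(1.5, 5.0), r_dis=(15.0, 55.0),
        c_hyp=(1.5, 6.0), k_z=(0.8e-6, 2.5e-6), kbar=(0.65, 2.2),
        h_sml=(1.5, 5.5), r_max=(120.0, 200.0), p_net=(80.0, 450.0),
        cv=0.45,
    ),
    "oligotrophic": dict(
        f_a=(0.05, 0.5), f_s=(0.1, 0.45), r_dis=(0.0, 0.0),
        c_hyp=(0.1, 0.7), k_z=(0.6e-6, 6e-6), kbar=(1.1, 3.3),
        h_sml=(0.9, 6.1), r_max=(150.0, 280.0), p_net=(2.0, 30.0),
        cv=0.45,
    ),
}


@dataclass
class SyntheticLakeSpec:
    """Recipe for one synthetic lake + campaign."""

    preset: str = "eutrophic"
    seed: int = 0
    r_s_fraction: float = 0.6  # r_s / r_max
    transect_noise_sd: float = 0.05  # multiplicative lognormal sigma
    ctd_noise_c: float = 0.02
    chamber_noise_ppm: float = 0.5

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if not 0.0 < self.r_s_fraction < 1.0:
            raise ValueError("r_s fraction must lie in (0, 1)")


@dataclass
class SyntheticLake:
    morph: LakeMorphometry
    geom: RadialGeometry
    fluxes: FluxSet
    truth: dict  # ground-truth parameters used to generate everything
    c_eq: float  # air-equilibrium CH4 used in the forward model, mmol m-3


def make_lake(spec: SyntheticLakeSpec) -> SyntheticLake:
    """Draw an internally consistent lake from the preset ranges.

    Geometry: a disk of radius r_max with pelagic mixed-layer depth H_SML
    and the littoral SML thinning linearly to the shore; areas, radii and
    the SML volume are mutually consistent by construction.
    """
    p = PRESETS[spec.preset]
    rng = np.random.default_rng(spec.seed)

    def draw(key):
        lo, hi = p[key]
        return float(rng.uniform(lo, hi))

    r_max = draw("r_max")
    h_sml = draw("h_sml")
    r_s = spec.r_s_fraction * r_max
    if r_s >= r_max:
        raise ValueError("pelagic radius must be smaller than the lake radius")
    geom = RadialGeometry(r_max=r_max, r_s=r_s, h_sml=h_sml)
    a_surface = np.pi * r_max**2
    a_sml_base = np.pi * r_s**2
    a_sediment = a_surface - a_sml_base  # SML-exposed littoral ring
    v_sml = sml_volume_of_revolution(geom)
    morph = LakeMorphometry(
        a_surface=a_surface,
        a_sediment=a_sediment,
        a_sml_base=a_sml_base,
        v_sml=v_sml,
        altitude_m=1750.0,
    )
    cv = p["cv"]
    f_s = draw("f_s")
    r_dis = draw("r_dis")
    c_hyp = draw("c_hyp")
    k_z = draw("k_z")
    kbar = draw("kbar")
    p_net = draw("p_net")
    c_eq = 0.003  # mmol m-3, ~air equilibrium at alpine pressure

    # F_a and F_z are not free: at steady state they are the surface and
    # SML-base exchanges the forward model implies. Deriving them keeps the
    # boundary-flux table consistent with the lake's true P_net, the way a
    # field campaign's chamber and gradient measurements would be.
    from .lateral import implied_boundary_fluxes  # local import: no cycle at load

    inputs = LateralInputs(
        k_h_m2_d=kh_peeters(r_s)[1], k_z_m2_s=k_z, kbar_m_d=kbar,
        c_hyp=c_hyp, c_eq=c_eq, f_s=f_s, r_dis_umol=r_dis,
    )
    sol = lateral_steady_solve(geom, inputs, p_net)
    implied = implied_boundary_fluxes(geom, inputs, sol, p_net)
    f_a = implied["f_a_mean"]
    f_z = implied["f_z_mean"]
    fx = FluxSet(
        f_s=Uncertain(f_s, cv * f_s),
        f_a=Uncertain(f_a, cv * abs(f_a)),
        f_z=Uncertain(f_z, cv * abs(f_z)),
        r_dis=Uncertain(r_dis, 0.2 * r_dis),
        c_hyp=c_hyp,
        k_z=k_z,
        kbar_ch4=kbar,
        k_h=inputs.k_h_m2_d,
    )
    truth = {
        "preset": spec.preset,
        "seed": spec.seed,
        "p_net_umol": p_net,
        "h_sml": h_sml,
        "r_max": r_max,
        "r_s": r_s,
    }
    return SyntheticLake(morph=morph, geom=geom, fluxes=fx, truth=truth, c_eq=c_eq)


def simulate_transect(
    lake: SyntheticLake,
    true_p_net: float | None = None,
    n_stations: int = 11,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_cells: int = 200,
) -> Transect:
    """Forward-model a surface transect and add multiplicative lognormal noise.

    Stations span center to shore (the folded shore-to-shore layout); ground
    truth is the steady lateral-model curve at ``true_p_net`` (defaults to
    the lake's own truth).
    """
    p_net = lake.truth["p_net_umol"] if true_p_net is None else true_p_net
    inputs = lake.fluxes.lateral_inputs(lake.c_eq)
    sol = lateral_steady_solve(lake.geom, inputs, p_net, n_cells)
    r = np.linspace(0.0, lake.geom.r_max * 0.98, n_stations)
    c = sol.interp(r)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        c = c * np.exp(rng.normal(0.0, noise_sd, size=c.size))
    return Transect(r_m=r, c_mmol_m3=c)


def make_temperature_profile(
    h_sml: float | None = 5.2,
    depth_max: float = 10.0,
    grid: float = 0.25,
    t_surface: float = 18.0,
    gradient: float = -3.0,
    overturn_depth: float | None = None,
    overturn_height: float = 0.0,
    noise: float = 0.02,
    seed: int = 0,
) -> TemperatureProfile:
    """Two-layer cast with an optional inserted overturn.

    With ``h_sml`` set, temperature is uniform above it and declines at
    ``gradient`` (degC m-1, negative) below; ``h_sml=None`` yields a linearly
    stratified cast from the surface. An overturn is a block reversal of the
    ``overturn_height``-tall segment starting at ``overturn_depth``.
    """
    z = np.arange(0.0, depth_max + grid / 2, grid)
    if h_sml is None:
        t = t_surface + gradient * z
    else:
        t = np.where(z <= h_sml, t_surface, t_surface + gradient * (z - h_sml))
    t = np.maximum(t, 4.0)
    if overturn_height > 0:
        if overturn_depth is None:
            overturn_depth = (h_sml or 0.0) + 1.0
        mask = (z >= overturn_depth) & (z <= overturn_depth + overturn_height)
        idx = np.nonzero(mask)[0]
        t[idx] = t[idx][::-1]
    rng = np.random.default_rng(seed)
    if noise > 0:
        t = t + rng.normal(0.0, noise, size=t.size)
    return TemperatureProfile(depth_m=z, temp_c=t)


def make_chamber_series(
    flux: float,
    volume_m3: float = 0.01,
    area_m2: float = 0.07,
    t_a: float = 293.15,
    p_atm: float = 81000.0,
    duration_s: float = 360.0,
    c0_ppm: float = 2.0,
    noise_ppm: float = 0.0,
    seed: int = 0,
):
    """Linear chamber accumulation curve for a known flux (mmol m-2 d-1).

    Returns (time_s, ppm); the slope is the ideal-gas inverse of the
    chamber-flux conversion, so a noise-free series round-trips exactly.
    """
    t = np.arange(0.0, duration_s, 1.0)
    slope = flux * 1e-3 / 86400.0 * area_m2 * R_GAS * t_a / (p_atm * volume_m3) * 1e6
    ppm = c0_ppm + slope * t
    rng = np.random.default_rng(seed)
    if noise_ppm > 0:
        ppm = ppm + rng.normal(0.0, noise_ppm, size=ppm.size)
    return t, ppm


def make_benthic_series(
    f_s: float,
    k_bc: float,
    v_water: float = 1.5e-3,
    v_air: float = 2.0e-4,
    a_chamber: float = 2.8e-3,
    t_a: float = 293.15,
    h_cp: float = 1.5e-5,
    c_w0: float = 1.0,
    p0: float = 0.2,
    duration_h: float = 1.0,
    dt_s: float = 5.0,
    noise_mult: float = 0.0,
    seed: int = 0,
) -> BenthicIncubation:
    """Closed benthic-chamber incubation from the transient balance.

    ``f_s`` in mmol m-2 d-1, ``k_bc`` in m d-1; the headspace curve is the
    closed-form solution, water endpoints follow from CH4 conservation, and
    ``noise_mult`` applies multiplicative Gaussian noise to the pressures.
    """
    t_d = np.arange(0.0, duration_h / 24.0 + dt_s / 86400.0 / 2, dt_s / 86400.0)
    w = a_chamber / v_water
    a = a_chamber / v_air
    b = w - h_cp * R_GAS * t_a * a
    c0 = c_w0 * 1e-3 - h_cp * p0
    p = transient_headspace_curve(t_d, p0, f_s * 1e-3, k_bc, c0, w, a, b, R_GAS * t_a)
    # water endpoint from conservation: added = headspace gain + water gain
    n_added = a_chamber * f_s * 1e-3 * t_d[-1]
    n_head = v_air / (R_GAS * t_a) * (p[-1] - p0)
    c_w_end = c_w0 + (n_added - n_head) / v_water * 1e3
    rng = np.random.default_rng(seed)
    if noise_mult > 0:
        p = p * (1.0 + rng.normal(0.0, noise_mult, size=p.size))
    return BenthicIncubation(
        time_d=t_d, p_ch4=p, v_water=v_water, v_air=v_air, a_chamber=a_chamber,
        t_a=t_a, h_cp=h_cp, c_w0=c_w0, c_w_end=float(c_w_end),
    )


def write_input_bundle(spec: SyntheticLakeSpec, outdir) -> "Path":
    """Write a complete synthetic input bundle a pipeline run consumes.

    Produces temperature_profile.csv, transect.csv and config.yaml in
    ``outdir`` and returns the config path. The attached ground truth is
    echoed into the config under ``truth`` for downstream recovery checks.
    """
    from pathlib import Path

    import yaml

    from .io import write_two_column

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lake = make_lake(spec)
    rng_seed = spec.seed

    prof = make_temperature_profile(
        h_sml=lake.geom.h_sml,
        depth_max=lake.geom.h_sml + 5.0,
        noise=spec.ctd_noise_c,
        seed=rng_seed,
    )
    write_two_column(outdir / "temperature_profile.csv", prof.depth_m, prof.temp_c,
                     ("depth_m", "temp_C"))

    transect = simulate_transect(lake, noise_sd=spec.transect_noise_sd, seed=rng_seed + 1)
    write_two_column(outdir / "transect.csv", transect.r_m, transect.c_mmol_m3,
                     ("r_m", "C_CH4"))

    fx = lake.fluxes
    cfg = {
        "lake": {
            "A_a": float(lake.morph.a_surface),
            "A_s": float(lake.morph.a_sediment),
            "A_z": float(lake.morph.a_sml_base),
            "V_SML": float(lake.morph.v_sml),
            "altitude_m": float(lake.morph.altitude_m),
        },
        "campaigns": {
            "synthetic": {
                "H_SML": float(lake.geom.h_sml),
                "t_water_c": 15.0,
                "temperature_profile": str(outdir / "temperature_profile.csv"),
                "transect": str(outdir / "transect.csv"),
                "fluxes": {
                    "F_s": [fx.f_s.mean, fx.f_s.sd],
                    "F_a": [fx.f_a.mean, fx.f_a.sd],
                    "F_z": [fx.f_z.mean, fx.f_z.sd],
                    "R_dis": [fx.r_dis.mean, fx.r_dis.sd],
                    "C_hyp": fx.c_hyp,
                    "K_z": fx.k_z,
                    "k_CH4": fx.kbar_ch4,
                    "K_H": fx.k_h,
                },
            }
        },
        "mc": {"seed": rng_seed, "n_iter": 10_000},
        "truth": lake.truth,
        "output_dir": str(outdir),
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path


def make_porewater_profile(
    slope_mmol_m4: float = 1e4,
    c_swi: float = 50.0,
    linear_cm: float = 3.0,
    depth_max_cm: float = 15.0,
    step_cm: float = 1.0,
    tail_scale_cm: float = 4.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> PorewaterProfile:
    """Porewater CH4 profile: linear top segment, saturating exponential tail.

    ``slope_mmol_m4`` is the concentration gradient over the linear top
    segment (mmol m-3 per m).
    """
    z = np.arange(0.0, depth_max_cm + step_cm / 2, step_cm)
    c_lin = c_swi + slope_mmol_m4 * z * 1e-2
    c_break = c_swi + slope_mmol_m4 * linear_cm * 1e-2
    amp = slope_mmol_m4 * tail_scale_cm * 1e-2  # slope-continuous tail
    c_tail = c_break + amp * (1.0 - np.exp(-(z - linear_cm) / tail_scale_cm))
    c = np.where(z <= linear_cm, c_lin, c_tail)
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        c = c * (1.0 + rng.normal(0.0, noise_frac, size=c.size))
    return PorewaterProfile(depth_cm=z, ch4_mmol_m3=np.maximum(c, 0.0))
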