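"""Bubble-mediated CH4 transport.

Three pieces:

* a discrete single-bubble dissolution model — a bubble of given initial
  diameter and composition rises from the sediment, exchanging CH4, CO2, O2
  and N2 with the water column; gas-side transfer uses a Sherwood
  correlation (Sh = 2 + 0.6 Re^1/2 Sc^1/3 by default) and rise speed a
  piecewise clean-bubble terminal-velocity fit, both replaceable callables;
* the aggregation of per-depth bubble dissolution into the volumetric SML
  dissolution rate R_dis(z);
* a steady two-layer sediment gas model that partitions CH4 production into
  the diffusive SWI flux and ebullition: production and diffusion balance in
  a thin non-ebullitive surface layer, while below it free gas forms
  (ebullition sink E(z)) whenever the total dissolved-gas pressure would
  exceed the local critical pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import solve_banded

from .constants import (
    GRAVITY,
    R_GAS,
    SECONDS_PER_DAY,
    T_KELVIN,
    henry_cp,
    molecular_diffusivity,
)

GASES = ("CH4", "CO2", "O2", "N2")


def kinematic_viscosity(temp_c) -> float:
    """Kinematic viscosity of water (m2 s-1), empirical fit 0-40 degC."""
    t = np.asarray(temp_c, dtype=float)
    return 1.79e-6 / (1.0 + 0.0337 * t + 0.000221 * t**2)


def terminal_velocity(radius_m: float) -> float:
    """Clean-bubble terminal rise speed (m s-1), piecewise in radius."""
    r = radius_m
    if r <= 7e-4:
        return 4474.0 * r**1.357
    if r <= 5.1e-3:
        return 0.23
    return 4.202 * r**0.547


def sherwood_transfer(radius_m: float, v_b: float, diffusivity: float, nu: float) -> float:
    """Gas-side transfer velocity k_b (m s-1) from Sh = 2 + 0.6 Re^1/2 Sc^1/3."""
    re = 2.0 * radius_m * v_b / nu
    sc = nu / diffusivity
    sh = 2.0 + 0.6 * np.sqrt(re) * sc ** (1.0 / 3.0)
    return sh * diffusivity / (2.0 * radius_m)


@dataclass
class WaterColumn:
    """Ambient profiles the bubble exchanges with (depth positive down)."""

    depth_m: np.ndarray
    temp_c: np.ndarray
    conc_mmol_m3: dict  # per gas, arrays on the depth grid
    p_surface: float = 101325.0  # Pa

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        for g in GASES:
            if g not in self.conc_mmol_m3:
                self.conc_mmol_m3[g] = np.zeros_like(self.depth_m)
            self.conc_mmol_m3[g] = np.asarray(self.conc_mmol_m3[g], dtype=float)

    def pressure(self, z):
        """Hydrostatic + atmospheric pressure (Pa); strictly increasing in z."""
        return self.p_surface + 998.0 * GRAVITY * np.asarray(z, dtype=float)

    def interp(self, z, what):
        return np.interp(z, self.depth_m, what)


@dataclass
class BubbleSpec:
    """A single representative bubble released at the sediment surface."""

    release_depth_m: float
    diameter_m: float = 5e-3
    fractions: dict = field(default_factory=lambda: {"CH4": 0.7, "N2": 0.3})

    def __post_init__(self) -> None:
        fr = {g: float(self.fractions.get(g, 0.0)) for g in GASES}
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"initial mole fractions sum to {total}, not 1")
        if any(v < 0 or v > 1 for v in fr.values()):
            raise ValueError("mole fractions must lie in [0, 1]")
        if self.diameter_m <= 0:
            raise ValueError("bubble diameter must be positive")
        self.fractions = fr

    def initial_moles(self, wc: WaterColumn) -> dict:
        """Per-gas moles at release from diameter, local pressure, temperature."""
        z = self.release_depth_m
        p = float(wc.pressure(z))
        t_k = float(wc.interp(z, wc.temp_c)) + T_KELVIN
        vol = 4.0 / 3.0 * np.pi * (self.diameter_m / 2.0) ** 3
        n_tot = p * vol / (R_GAS * t_k)
        return {g: n_tot * self.fractions[g] for g in GASES}


@dataclass
class RiseResult:
    depth_grid: np.ndarray  # layer mid-depths, m (release -> surface)
    dissolved_mol: dict  # net moles transferred to water per layer, per gas
    surfacing_mol: dict  # per gas, at the surface (zeros if fully dissolved)
    initial_mol: dict
    r_sml_umol: float  # CH4 dissolved within the SML, umol per bubble
    beta: float  # fraction of initial CH4 dissolved within the SML
    fully_dissolved: bool = False


def rise_and_dissolve(
    bubble: BubbleSpec,
    wc: WaterColumn,
    sml_base_m: float,
    dz: float = 0.05,
    velocity=terminal_velocity,
    transfer=sherwood_transfer,
) -> RiseResult:
    """Integrate a rising bubble from its release depth to the surface.

    Midpoint (RK2) stepping in depth; per step and gas the exchange is
    A_bubble * k_b * (H_cp * P_bub * x_i - C_water), shrinking or feeding the
    bubble. Returns the per-layer net dissolution, the surfacing composition,
    and the CH4 dissolved within the SML (r_i).
    """
    if not 0.0 <= bubble.release_depth_m <= wc.depth_m.max() + 1e-9:
        raise ValueError("release depth outside the water column")
    n = {g: v for g, v in bubble.initial_moles(wc).items()}
    initial = dict(n)
    z = bubble.release_depth_m
    depths, dissolved = [], {g: [] for g in GASES}
    r_sml = 0.0
    fully = False

    def rates(zz, moles):
        """d(moles)/dz per gas (positive = leaving bubble) and rise speed."""
        t_c = float(wc.interp(zz, wc.temp_c))
        p = float(wc.pressure(zz))
        n_tot = sum(max(m, 0.0) for m in moles.values())
        if n_tot <= 0.0:
            return None, 0.0
        vol = n_tot * R_GAS * (t_c + T_KELVIN) / p
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        v_b = velocity(r)
        nu = kinematic_viscosity(t_c)
        area = 4.0 * np.pi * r**2
        out = {}
        for g in GASES:
            x = max(moles[g], 0.0) / n_tot
            c_eq = float(henry_cp(g, t_c)) * p * x  # mol m-3
            c_w = float(wc.interp(zz, wc.conc_mmol_m3[g])) * 1e-3
            k_b = transfer(r, v_b, float(molecular_diffusivity(g, t_c)), nu)
            out[g] = area * k_b * (c_eq - c_w) / v_b  # mol per m of rise
        return out, v_b

    while z > 1e-12:
        step = min(dz, z)
        rate1, _ = rates(z, n)
        if rate1 is None:
            fully = True
            break
        n_mid = {g: n[g] - 0.5 * step * rate1[g] for g in GASES}
        rate2, _ = rates(z - 0.5 * step, n_mid)
        if rate2 is None:
            rate2 = rate1
        loss = {}
        for g in GASES:
            dl = step * rate2[g]
            loss[g] = min(dl, n[g]) if dl > 0 else dl  # cannot lose more than held
        depths.append(z - 0.5 * step)
        for g in GASES:
            n[g] -= loss[g]
            dissolved[g].append(loss[g])
            if n[g] < 0:  # numerical guard; conservation enforced via loss clip
                raise RuntimeError("negative bubble gas content — step size too large")
        if z - 0.5 * step <= sml_base_m:
            r_sml += loss["CH4"]
        z -= step
        if sum(n.values()) <= 1e-9 * sum(initial.values()):
            fully = True
            break

    if fully:
        # remaining inventory counted as dissolved at the terminal depth
        if z <= sml_base_m:
            r_sml += n["CH4"]
        for g in GASES:
            if depths:
                dissolved[g][-1] += n[g]
        n = {g: 0.0 for g in GASES}

    n0_ch4 = initial["CH4"]
    return RiseResult(
        depth_grid=np.asarray(depths),
        dissolved_mol={g: np.asarray(v) for g, v in dissolved.items()},
        surfacing_mol=n,
        initial_mol=initial,
        r_sml_umol=r_sml * 1e6,
        beta=r_sml / n0_ch4 if n0_ch4 > 0 else 0.0,
        fully_dissolved=fully,
    )


# -- Eq.-12-style aggregation -------------------------------------------------


@dataclass
class EbullitionField:
    """Per-depth-bin ebullition released at the SWI and its SML dissolution."""

    bin_depth_m: np.ndarray  # release depth of each bin (m)
    f_eb_swi: np.ndarray  # CH4 ebullition flux at the SWI, mmol m-2 d-1
    delta_a_sed: np.ndarray  # sediment area of each bin, m2
    r_umol: np.ndarray  # CH4 dissolved in the SML per bubble from bin i, umol
    n0_umol: np.ndarray  # initial CH4 per bubble released at bin i, umol

    def __post_init__(self) -> None:
        for name in ("bin_depth_m", "f_eb_swi", "delta_a_sed", "r_umol", "n0_umol"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.f_eb_swi < 0):
            raise ValueError("ebullition fluxes must be non-negative")


def rdis_profile(field: EbullitionField, z: float, a_planar_m2: float) -> float:
    """Bubble dissolution rate R_dis at depth z (umol m-3 d-1).

    Sums r_i * (F_eb,SWI,i / n_0,i) * dA_sed,i over all bins released below
    z, normalized by the planar area at z. F_eb/n_0 is the bubble number
    flux (bubbles m-2 d-1) since both are per-bubble CH4 amounts.
    """
    if a_planar_m2 <= 0:
        raise ValueError("planar area must be positive")
    mask = field.bin_depth_m >= z
    if not np.any(mask):
        return 0.0
    number_flux = np.divide(
        field.f_eb_swi[mask] * 1e3,  # mmol -> umol m-2 d-1
        field.n0_umol[mask],
        out=np.zeros(int(mask.sum())),
        where=field.n0_umol[mask] > 0,
    )
    total = np.sum(field.r_umol[mask] * number_flux * field.delta_a_sed[mask])
    return float(total / a_planar_m2)


# -- two-layer sediment ebullition model -------------------------------------


@dataclass
class SedimentColumn:
    """Steady sediment gas column for the ebullition partition model.

    CH4 production is W(z) = W0 exp(-z/lambda); other gases are produced
    nowhere and only diffuse/strip. ``c_top`` holds the dissolved
    concentrations of the overlying water (mol m-3).
    """

    depth_max_m: float = 0.3
    n_nodes: int = 121
    porosity: float = 0.9
    tortuosity2: float = 1.2
    temp_c: float = 10.0
    lambda_m: float = 0.05  # e-folding depth of CH4 production
    z_eb_min: float = 0.02  # non-ebullitive surface layer thickness, m
    water_depth_m: float = 5.0  # site depth, sets the critical pressure
    p_surface: float = 101325.0
    c_top: dict = field(default_factory=dict)
    gases: tuple = ("CH4", "N2")

    def __post_init__(self) -> None:
        self.z = np.linspace(0.0, self.depth_max_m, self.n_nodes)
        self.dz = self.z[1] - self.z[0]
        for g in self.gases:
            self.c_top.setdefault(g, 0.0)
        #: critical gas pressure: hydrostatic + atmospheric at the site
        self.p_crit = self.p_surface + 998.0 * GRAVITY * self.water_depth_m

    def henry_volatility(self, gas: str) -> float:
        """K_H,i = 1/H_cp, Pa m3 mol-1 at the column temperature."""
        return 1.0 / float(henry_cp(gas, self.temp_c))

    def diffusivity_m2_d(self, gas: str) -> float:
        return float(molecular_diffusivity(gas, self.temp_c)) * SECONDS_PER_DAY / self.tortuosity2

    def production(self, w0: float, gas: str) -> np.ndarray:
        if gas == "CH4":
            return w0 * np.exp(-self.z / self.lambda_m)
        return np.zeros_like(self.z)


@dataclass
class EbullitionSolution:
    conc: dict  # mol m-3 per gas on the column grid
    e_rate: np.ndarray  # total gas ebullition per bulk volume, mol m-3 d-1
    f_diff_swi: float  # diffusive CH4 flux at the SWI, mmol m-2 d-1
    f_eb_swi: float  # CH4 ebullition flux at the SWI, mmol m-2 d-1
    w0: float  # calibrated CH4 production amplitude, mol m-3 d-1
    no_ebullition: bool = False


def _solve_gas(col: SedimentColumn, gas: str, w0: float, e_rate: np.ndarray) -> np.ndarray:
    """Tridiagonal solve of phi D C'' + W - E K_H C / P = 0 for one gas."""
    n = col.n_nodes
    dz2 = col.dz**2
    phi_d = col.porosity * col.diffusivity_m2_d(gas)
    k_h = col.henry_volatility(gas)
    w = col.production(w0, gas)
    sink = e_rate * k_h / col.p_crit  # d-1 coefficient on C
    main = np.full(n, -2.0 * phi_d / dz2) - sink
    lower = np.full(n - 1, phi_d / dz2)
    upper = np.full(n - 1, phi_d / dz2)
    rhs = -w
    # Dirichlet top (C = overlying water), no-flux bottom (ghost reflection)
    main[0] = 1.0
    upper[0] = 0.0
    rhs[0] = col.c_top[gas]
    lower[-1] = 2.0 * phi_d / dz2
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


def _saturation_solve(
    col: SedimentColumn,
    w0: float,
    dt_d: float = 5.0,
    max_steps: int = 6000,
    tol: float = 1e-8,
):
    """March the column to steady state under the saturation constraint.

    Implicit-Euler diffusion steps per gas, then proportional clipping
    wherever the total dissolved-gas pressure exceeds the critical pressure
    in the ebullitive zone. Clipping removes each gas in proportion to its
    partial-pressure contribution — exactly the E * K_H,i C_i / P sink — and
    the removal rate at steady state is the ebullition field E(z).

    Returns (conc, e_rate, removal_per_gas) with rates in mol m-3 d-1.
    """
    n = col.n_nodes
    dz2 = col.dz**2
    ebul = col.z > col.z_eb_min
    k_h = {g: col.henry_volatility(g) for g in col.gases}
    w = {g: col.production(w0, g) for g in col.gases}

    mats = {}
    for g in col.gases:
        phi_d = col.porosity * col.diffusivity_m2_d(g)
        ab = np.zeros((3, n))
        ab[1, :] = 1.0 / dt_d + 2.0 * phi_d / dz2
        ab[0, 1:] = -phi_d / dz2
        ab[2, :-1] = -phi_d / dz2
        ab[1, 0] = 1.0  # Dirichlet top
        ab[0, 1] = 0.0
        ab[2, -2] = -2.0 * phi_d / dz2  # no-flux bottom (ghost reflection)
        mats[g] = ab

    # start from the no-ebullition steady profile; clipping then carves E in
    conc = {g: _solve_gas(col, g, w0, np.zeros(n)) for g in col.gases}
    removal = {g: np.zeros(n) for g in col.gases}
    scale = max(w0, 1e-12)
    for _ in range(max_steps):
        new = {}
        for g in col.gases:
            rhs = conc[g] / dt_d + w[g]
            rhs[0] = col.c_top[g]
            new[g] = solve_banded((1, 1), mats[g], rhs)
        p_tot = sum(k_h[g] * new[g] for g in col.gases)
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(ebul & (p_tot > col.p_crit), col.p_crit / p_tot, 1.0)
        rate = 0.0
        for g in col.gases:
            removal[g] = new[g] * (1.0 - shrink) / dt_d
            clipped = new[g] * shrink
            rate = max(rate, float(np.max(np.abs(clipped - conc[g]))) / dt_d)
            conc[g] = clipped
        if rate < tol * scale:
            break
    e_rate = sum(removal[g] for g in col.gases)
    return conc, e_rate, removal


def _swi_diffusive_flux(col: SedimentColumn, c_ch4: np.ndarray) -> float:
    """Upward diffusive CH4 flux at z=0 (mmol m-2 d-1), one-sided 2nd order."""
    phi_d = col.porosity * col.diffusivity_m2_d("CH4")
    dcdz = (-3.0 * c_ch4[0] + 4.0 * c_ch4[1] - c_ch4[2]) / (2.0 * col.dz)
    return float(phi_d * dcdz * 1e3)


def sediment_ebullition(col: SedimentColumn, f_s_target: float) -> EbullitionSolution:
    """Partition sediment CH4 production into SWI diffusion and ebullition.

    The production amplitude W0 is calibrated so the diffusive SWI flux
    equals ``f_s_target`` (mmol m-2 d-1); the ebullitive CH4 flux is the
    depth integral of the stripping sink E * K_H * C / P for CH4.
    """
    if f_s_target < 0:
        raise ValueError("target sediment flux must be non-negative")
    if f_s_target == 0.0:
        conc = {g: _solve_gas(col, g, 0.0, np.zeros(col.n_nodes)) for g in col.gases}
        return EbullitionSolution(conc, np.zeros(col.n_nodes), 0.0, 0.0, 0.0, no_ebullition=True)

    # W0 that would give the target flux with zero ebullition (all production
    # diffuses out at steady state with a no-flux bottom)
    integral = col.lambda_m * (1.0 - np.exp(-col.depth_max_m / col.lambda_m))
    w0_base = f_s_target * 1e-3 / integral

    def flux_error(w0):
        conc, _, _ = _saturation_solve(col, w0)
        return _swi_diffusive_flux(col, conc["CH4"]) - f_s_target

    lo, hi = 0.5 * w0_base, w0_base
    err_hi = flux_error(hi)
    tries = 0
    while err_hi < 0 and tries < 30:
        hi *= 1.6
        err_hi = flux_error(hi)
        tries += 1
    if flux_error(lo) > 0:
        lo = 1e-6 * w0_base
    w0 = optimize.brentq(flux_error, lo, hi, xtol=1e-12, rtol=1e-8, maxiter=200)
    conc, e_rate, removal = _saturation_solve(col, w0)
    f_diff = _swi_diffusive_flux(col, conc["CH4"])
    f_eb = float(np.trapezoid(removal["CH4"], col.z) * 1e3)
    no_eb = bool(np.all(e_rate == 0.0))
    return EbullitionSolution(conc, e_rate, f_diff, f_eb, w0, no_ebullition=no_eb)


def feb_needed(p_net_umol: float, v_sml_m3: float, beta: float, a_sed_m2: float) -> float:
    """Ebullition flux needed to sustain P_net via bubble dissolution alone.

    F_eb,need = P_net * V_SML / (beta * A_sed), returned in mmol m-2 d-1.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta (fraction of ebullition dissolved in the SML) must be in (0, 1]")
    if a_sed_m2 <= 0:
        raise ValueError("sediment area must be positive")
    return p_net_umol * v_sml_m3 / (beta * a_sed_m2) * 1e-3
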