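"""Littoral sediment CH4 fluxes.

Two independent routes: (1) Fick's first law on the linear top segment of a
porewater profile, and (2) closed benthic-chamber incubations evaluated by
three mass-balance methods — integrated (endpoints), transient (fit of the
full headspace curve), and equilibrium (tail slope) — which are averaged into
a chamber estimate. The combined littoral flux is the unweighted mean of the
porewater and chamber estimates.

The transient chamber balance for the headspace partial pressure P(t) is

    dP/dt = (a R T_a / b) * (w F_s - (w F_s - b k_bc C_0) exp(-b k_bc t))

with w = A_bc/V_w, a = A_bc/V_air, b = w - H_cp R T_a a and
C_0 = C_w(0) - H_cp P(0). We fit its closed-form integral to P(t) rather
than differentiating a noisy 1 Hz series; the fitted (F_s, k_bc) are the
same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import R_GAS

#: molecular diffusivity of CH4 in water used in the porewater method, m2 s-1
D_CH4_POREWATER = 1.5e-9  # = 1.5e-5 cm2 s-1


@dataclass
class PorewaterProfile:
    """Porewater CH4 vs. sediment depth below the sediment-water interface."""

    depth_cm: np.ndarray
    ch4_mmol_m3: np.ndarray
    porosity: float = 0.9
    tortuosity2: float = 1.2
    d_ch4_m2_s: float = D_CH4_POREWATER

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.ch4_mmol_m3 = np.asarray(self.ch4_mmol_m3, dtype=float)
        if np.any(np.diff(self.depth_cm) <= 0):
            raise ValueError("sediment depths must be increasing")
        if np.any(self.ch4_mmol_m3 < 0):
            raise ValueError("porewater concentrations must be non-negative")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")


def porewater_fick(p: PorewaterProfile, top_cm: float = 3.0) -> float:
    """Diffusive SWI flux F_s = -phi * D * theta^-2 * dC/dz (mmol m-2 d-1).

    dC/dz is the OLS slope over the top ``top_cm`` of the profile; positive
    flux means efflux out of the sediment (concentration increasing with
    sediment depth).
    """
    mask = p.depth_cm <= top_cm + 1e-12
    z = p.depth_cm[mask] * 1e-2  # m
    c = p.ch4_mmol_m3[mask]
    if z.size < 2:
        raise ValueError(f"need >= 2 porewater points within the top {top_cm} cm")
    if np.ptp(c) == 0.0:
        return 0.0
    slope = stats.linregress(z, c).slope  # mmol m-4
    flux = p.porosity * p.d_ch4_m2_s / p.tortuosity2 * slope  # mmol m-2 s-1
    return float(flux * 86400.0)


@dataclass
class BenthicIncubation:
    """A closed benthic-chamber (core incubation) record, ~1 h at ~1 Hz."""

    time_d: np.ndarray  # days since lid closure
    p_ch4: np.ndarray  # headspace CH4 partial pressure, Pa
    v_water: float  # m3
    v_air: float  # m3
    a_chamber: float  # cross-section, m2
    t_a: float = 293.15  # K
    h_cp: float = 1.5e-5  # mol m-3 Pa-1 at incubation temperature
    c_w0: float | None = None  # dissolved CH4 at start, mmol m-3
    c_w_end: float | None = None  # dissolved CH4 at end, mmol m-3

    w: float = field(init=False)
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        self.time_d = np.asarray(self.time_d, dtype=float)
        self.p_ch4 = np.asarray(self.p_ch4, dtype=float)
        if self.v_water <= 0 or self.v_air <= 0 or self.a_chamber <= 0:
            raise ValueError("volumes and chamber area must be positive")
        self.w = self.a_chamber / self.v_water
        self.a = self.a_chamber / self.v_air
        self.b = self.w - self.h_cp * R_GAS * self.t_a * self.a

    @property
    def c0_mol(self) -> float:
        """C_0 = C_w(0) - H_cp P(0), in mol m-3."""
        if self.c_w0 is None:
            raise ValueError("initial dissolved concentration missing")
        return self.c_w0 * 1e-3 - self.h_cp * self.p_ch4[0]


def transient_headspace_curve(t, p0, f_s_mol, k_bc, c0, w, a, b, rt):
    """Closed-form headspace curve P(t): integral of the transient balance.

    P(t) = P0 + (aRT/b)[ wF_s t - (wF_s - b k C0) (1 - e^{-bkt})/(bk) ];
    at bk -> 0 the bracket degenerates to the k=0 linear balance.
    """
    t = np.asarray(t, dtype=float)
    rate_inf = (a * rt / b) * w * f_s_mol
    amp = (a * rt / b) * (w * f_s_mol - b * k_bc * c0)
    bk = b * k_bc
    if abs(bk) < 1e-12:
        expm = t
    else:
        expm = -np.expm1(-bk * t) / bk
    return p0 + rate_inf * t - amp * expm


def benthic_integrated(inc: BenthicIncubation) -> float:
    """Endpoint mass balance (mmol m-2 d-1).

    F_s A_bc = (V_air/(R T_a)) dP/dt + V_w dC_w/dt using only the first and
    last samples of each phase.
    """
    dt = inc.time_d[-1] - inc.time_d[0]
    if dt <= 0:
        raise ValueError("incubation duration must be positive")
    if inc.c_w0 is None or inc.c_w_end is None:
        raise ValueError("endpoint dissolved concentrations required")
    dp = inc.p_ch4[-1] - inc.p_ch4[0]
    dc = (inc.c_w_end - inc.c_w0) * 1e-3  # mol m-3
    n_rate = inc.v_air / (R_GAS * inc.t_a) * dp / dt + inc.v_water * dc / dt  # mol d-1
    return float(n_rate / inc.a_chamber * 1e3)


@dataclass
class TransientFit:
    f_s: float  # mmol m-2 d-1
    k_bc: float  # m d-1
    rmse_pa: float
    at_bound: bool = False


def benthic_transient(
    inc: BenthicIncubation,
    k_bounds: tuple[float, float] = (0.0, 40.0),
) -> TransientFit:
    """Fit (F_s, k_bc) to the full headspace curve (mmol m-2 d-1, m d-1).

    Nonlinear least squares on the closed-form P(t); k_bc constrained to the
    stated physical bounds, F_s unbounded below at 0.
    """
    if inc.c_w0 is None:
        raise ValueError("transient fit needs the initial dissolved concentration")
    t = inc.time_d - inc.time_d[0]
    p0 = inc.p_ch4[0]
    rt = R_GAS * inc.t_a
    c0 = inc.c0_mol
    if np.ptp(inc.p_ch4) == 0.0 and c0 == 0.0:
        return TransientFit(f_s=0.0, k_bc=0.0, rmse_pa=0.0)

    def model(tt, f_s_mol, k_bc):
        return transient_headspace_curve(tt, p0, f_s_mol, k_bc, c0, inc.w, inc.a, inc.b, rt)

    # initial guesses: endpoint slope for F_s, mid-range k
    slope0 = (inc.p_ch4[-1] - p0) / max(t[-1], 1e-9)
    f_s0 = max(slope0 * inc.b / (inc.a * rt * inc.w), 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            inc.p_ch4,
            p0=[f_s0, 0.5 * (k_bounds[0] + k_bounds[1])],
            bounds=([0.0, k_bounds[0]], [np.inf, k_bounds[1]]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = inc.p_ch4 - model(t, f_s0, 1.0)
        raise RuntimeError(
            f"transient fit did not converge (residual RMS {np.sqrt(np.mean(resid**2)):.3g} Pa)"
        ) from err
    f_s_mol, k_bc = popt
    resid = inc.p_ch4 - model(t, *popt)
    at_bound = bool(
        np.isclose(k_bc, k_bounds[0], atol=1e-6) or np.isclose(k_bc, k_bounds[1], atol=1e-6)
    )
    return TransientFit(
        f_s=float(f_s_mol * 1e3),
        k_bc=float(k_bc),
        rmse_pa=float(np.sqrt(np.mean(resid**2))),
        at_bound=at_bound,
    )


@dataclass
class EquilibriumEstimate:
    f_s: float  # mmol m-2 d-1
    low_confidence: bool = False


def benthic_equilibrium(inc: BenthicIncubation, tail_s: float = 300.0) -> EquilibriumEstimate:
    """Tail-slope estimate (mmol m-2 d-1).

    Once the exponential transient has decayed, P(t) grows linearly with
    slope (a R T_a / b) w F_s; the last ``tail_s`` seconds are used.
    """
    tail_d = tail_s / 86400.0
    mask = inc.time_d >= inc.time_d[-1] - tail_d
    t = inc.time_d[mask]
    p = inc.p_ch4[mask]
    if t.size < 3:
        raise ValueError("tail window holds fewer than 3 samples")
    if np.ptp(p) == 0.0:
        return EquilibriumEstimate(0.0, low_confidence=False)
    fit = stats.linregress(t, p)
    f_s_mol = fit.slope * inc.b / (inc.a * R_GAS * inc.t_a * inc.w)
    low_conf = bool(fit.stderr is not None and fit.stderr > abs(fit.slope))
    return EquilibriumEstimate(float(f_s_mol * 1e3), low_confidence=low_conf)


@dataclass
class SedimentFluxEstimate:
    """Combined littoral sediment flux with per-method detail (mmol m-2 d-1)."""

    per_method: dict
    chamber_mean: float | None
    combined: float
    sd: float


def combine_sediment_fluxes(
    porewater: float | None = None,
    integrated: float | None = None,
    transient: float | None = None,
    equilibrium: float | None = None,
) -> SedimentFluxEstimate:
    """Average the chamber methods, then average chamber with porewater.

    The chamber estimate is the mean of its available methods; the combined
    value is the unweighted mean of the independent estimates (porewater,
    chamber), with the SD taken across those independent estimates.
    """
    methods = {
        "porewater": porewater,
        "integrated": integrated,
        "transient": transient,
        "equilibrium": equilibrium,
    }
    chamber_vals = [v for k, v in methods.items() if k != "porewater" and v is not None]
    chamber = float(np.mean(chamber_vals)) if chamber_vals else None
    independent = [v for v in (porewater, chamber) if v is not None]
    if not independent:
        raise ValueError("no sediment-flux estimates supplied")
    combined = float(np.mean(independent))
    sd = float(np.std(independent, ddof=1)) if len(independent) > 1 else 0.0
    return SedimentFluxEstimate(
        per_method=methods, chamber_mean=chamber, combined=combined, sd=sd
    )
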