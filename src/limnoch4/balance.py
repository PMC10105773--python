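"""0-D full-scale SML methane budget, Monte Carlo uncertainty propagation,
source contributions, and the sensitivity analyses built on top of the two
P_net estimators.

The full-scale balance treats the SML as a well-mixed reactor at steady
state:

    0 = A_s F_s - A_a F_a + A_z F_z + R_dis V_SML + P_net V_SML   [mol d-1]

so P_net,fs = (A_a F_a - A_s F_s - A_z F_z)/V_SML - R_dis. Negative P_net
means net methane oxidation in the SML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .geometry import LakeMorphometry, RadialGeometry
from .lateral import LateralFit, LateralInputs, Transect, lateral_steady_solve, pnet_lateral_fit
from .surface import FitStats, compare_models


@dataclass
class Uncertain:
    """A measured quantity as mean +/- SD."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass
class FluxSet:
    """Per-campaign boundary fluxes of the SML budget (table-row analogue).

    F_s, F_a, F_z in mmol m-2 d-1; R_dis in umol m-3 d-1; C_hyp in mmol m-3;
    K_z in m2 s-1; kbar_CH4 in m d-1; K_H in m2 d-1.
    """

    f_s: Uncertain
    f_a: Uncertain
    f_z: Uncertain
    r_dis: Uncertain = field(default_factory=lambda: Uncertain(0.0))
    c_hyp: float = 0.0
    k_z: float = 0.0
    kbar_ch4: float = 1.0
    k_h: float = 1000.0
    dz: float = 1.0

    def __post_init__(self) -> None:
        if self.k_h <= 0:
            raise ValueError("horizontal dispersion K_H must be positive")

    def lateral_inputs(self, c_eq: float) -> LateralInputs:
        return LateralInputs(
            k_h_m2_d=self.k_h,
            k_z_m2_s=self.k_z,
            kbar_m_d=self.kbar_ch4,
            c_hyp=self.c_hyp,
            c_eq=c_eq,
            f_s=self.f_s.mean,
            r_dis_umol=self.r_dis.mean,
            dz_m=self.dz,
        )


def pnet_fullscale(morph: LakeMorphometry, fx: FluxSet) -> float:
    """Steady 0-D net production P_net,fs (umol m-3 d-1)."""
    if morph.v_sml <= 0:
        raise ValueError("SML volume must be positive")
    p_mmol = (
        morph.a_surface * fx.f_a.mean
        - morph.a_sediment * fx.f_s.mean
        - morph.a_sml_base * fx.f_z.mean
    ) / morph.v_sml - fx.r_dis.mean * 1e-3
    return p_mmol * 1e3  # -> umol m-3 d-1


def kh_peeters(length_m: float) -> tuple[float, float]:
    """Horizontal dispersion K_H = 1.4e-4 L^1.07; returns (m2 s-1, m2 d-1).

    L is the pelagic radius r_s of the lake.
    """
    if length_m <= 0:
        raise ValueError("length scale must be positive")
    k_si = 1.4e-4 * length_m**1.07
    return k_si, k_si * 86400.0


# -- Monte Carlo --------------------------------------------------------------


@dataclass
class MonteCarloConfig:
    n_iter: int = 10_000
    seed: int = 0


@dataclass
class PnetEstimate:
    point: float  # umol m-3 d-1
    samples: np.ndarray
    method: str  # 'fs' or 'lt'
    mean: float = field(init=False)
    sd: float = field(init=False)
    quartiles: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.mean = float(self.samples.mean())
        self.sd = float(self.samples.std(ddof=1)) if self.samples.size > 1 else 0.0
        self.quartiles = tuple(np.percentile(self.samples, [25, 50, 75]))


def gamma_draws(rng: np.random.Generator, u: Uncertain, n: int) -> np.ndarray:
    """Positive draws with the given mean and SD: gamma(k=mu^2/sd^2, th=sd^2/mu).

    A zero SD (or non-positive mean, where the gamma moment match is
    undefined) degenerates to the mean.
    """
    if u.sd == 0.0 or u.mean <= 0.0:
        return np.full(n, u.mean)
    shape = u.mean**2 / u.sd**2
    scale = u.sd**2 / u.mean
    return rng.gamma(shape, scale, size=n)


def normal_draws(rng: np.random.Generator, u: Uncertain, n: int) -> np.ndarray:
    if u.sd == 0.0:
        return np.full(n, u.mean)
    return rng.normal(u.mean, u.sd, size=n)


def monte_carlo_fullscale(
    morph: LakeMorphometry, fx: FluxSet, cfg: MonteCarloConfig
) -> PnetEstimate:
    """MC propagation of the 0-D budget: gamma F_a/F_s, normal F_z/R_dis."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iter
    f_a = gamma_draws(rng, fx.f_a, n)
    f_s = gamma_draws(rng, fx.f_s, n)
    f_z = normal_draws(rng, fx.f_z, n)
    r_dis = normal_draws(rng, fx.r_dis, n)
    samples = (
        morph.a_surface * f_a - morph.a_sediment * f_s - morph.a_sml_base * f_z
    ) / morph.v_sml * 1e3 - r_dis
    return PnetEstimate(point=pnet_fullscale(morph, fx), samples=samples, method="fs")


def monte_carlo_lateral(
    geom: RadialGeometry,
    fx: FluxSet,
    transect: Transect,
    c_eq: float,
    cfg: MonteCarloConfig,
    n_cells: int = 200,
) -> PnetEstimate:
    """MC for the lateral fit: re-fit P_net per draw of F_s, F_a, F_z.

    F_a and F_z have no direct term in the lateral balance; their draws scale
    the coefficients they parameterize (kbar with F_a, K_z with F_z), i.e.
    flux uncertainty maps to coefficient uncertainty at a fixed gradient.
    R_dis stays at its mean (its SML contribution is small).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iter
    f_s = gamma_draws(rng, fx.f_s, n)
    f_a = gamma_draws(rng, fx.f_a, n)
    f_z = normal_draws(rng, fx.f_z, n)
    point = pnet_lateral_fit(geom, fx.lateral_inputs(c_eq), transect, n_cells).p_net_umol
    samples = np.empty(n)
    for i in range(n):
        fx_i = replace(
            fx,
            f_s=Uncertain(f_s[i]),
            kbar_ch4=fx.kbar_ch4 * (f_a[i] / fx.f_a.mean if fx.f_a.mean != 0 else 1.0),
            k_z=fx.k_z * (f_z[i] / fx.f_z.mean if fx.f_z.mean != 0 else 1.0),
        )
        samples[i] = pnet_lateral_fit(geom, fx_i.lateral_inputs(c_eq), transect, n_cells).p_net_umol
    return PnetEstimate(point=point, samples=samples, method="lt")


# -- derived analyses ---------------------------------------------------------


SOURCE_NAMES = ("R_dis", "F_s", "P_net", "F_z")


def source_contributions(sources_mol_d) -> np.ndarray:
    """Percent contribution of each source term to total diffusive emission.

    Non-positive source terms are zeroed before normalizing, so the
    percentages always sum to 100 when at least one source is positive.
    """
    s = np.maximum(np.asarray(sources_mol_d, dtype=float), 0.0)
    total = s.sum()
    if total <= 0:
        raise ValueError("all source terms non-positive: contributions undefined")
    return 100.0 * s / total


def budget_sources(morph: LakeMorphometry, fx: FluxSet, p_net_umol: float) -> dict:
    """The four source terms of the emission budget, in mol d-1."""
    return {
        "R_dis": fx.r_dis.mean * 1e-6 * morph.v_sml,
        "F_s": fx.f_s.mean * 1e-3 * morph.a_sediment,
        "P_net": p_net_umol * 1e-6 * morph.v_sml,
        "F_z": fx.f_z.mean * 1e-3 * morph.a_sml_base,
    }


def pnet_error_propagation(
    fx: FluxSet,
    morph: LakeMorphometry,
    p_net_umol: float,
    k_err: float,
    atm_area: str = "sediment",
) -> tuple[float, float]:
    """Relative P_net error from a relative transfer-velocity error.

    P_net_err = (F_a A / (P_net V_SML)) * k_err, with A = A_s as printed in
    the source relation (``atm_area='surface'`` switches to A_a, the area the
    atmospheric term of the 0-D budget actually uses). Returns
    (p_net_err, slope).
    """
    if p_net_umol == 0:
        raise ValueError("P_net = 0: relative error undefined")
    area = morph.a_sediment if atm_area == "sediment" else morph.a_surface
    slope = fx.f_a.mean * 1e-3 * area / (p_net_umol * 1e-6 * morph.v_sml)
    return slope * k_err, slope


def fs_needed(morph: LakeMorphometry, fx: FluxSet) -> float:
    """Littoral sediment flux that would close the 0-D budget with P_net = 0.

    F_s,need = (A_a F_a - A_z F_z - R_dis V_SML) / A_s (mmol m-2 d-1).
    """
    if morph.a_sediment <= 0:
        raise ValueError("sediment area must be positive")
    return (
        morph.a_surface * fx.f_a.mean
        - morph.a_sml_base * fx.f_z.mean
        - fx.r_dis.mean * 1e-3 * morph.v_sml
    ) / morph.a_sediment


def fs_needed_mc(morph: LakeMorphometry, fx: FluxSet, cfg: MonteCarloConfig) -> np.ndarray:
    """Monte Carlo variant of :func:`fs_needed` propagating F_a, F_z, R_dis."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iter
    f_a = gamma_draws(rng, fx.f_a, n)
    f_z = normal_draws(rng, fx.f_z, n)
    r_dis = normal_draws(rng, fx.r_dis, n)
    return (
        morph.a_surface * f_a - morph.a_sml_base * f_z - r_dis * 1e-3 * morph.v_sml
    ) / morph.a_sediment


@dataclass
class SensitivityRow:
    label: str
    p_net_umol: float
    kbar_m_d: float
    stats: FitStats


def k600_sensitivity_suite(
    geom: RadialGeometry,
    fx: FluxSet,
    transect: Transect,
    c_eq: float,
    configs: list[tuple[str, float, float]],
    n_cells: int = 200,
    logspace: bool = True,
) -> list[SensitivityRow]:
    """Simulate the transect under (P_net, k_CH4) configurations.

    ``configs`` holds (label, p_net_umol, kbar_m_d) triples; each is run
    through the steady lateral model and compared against the measured
    stations (log10 space by default).
    """
    rows = []
    for label, p_net, kbar in configs:
        inputs = replace(fx.lateral_inputs(c_eq), kbar_m_d=kbar)
        fieldsol = lateral_steady_solve(geom, inputs, p_net, n_cells)
        pred = fieldsol.interp(transect.r_m)
        st = compare_models(pred, transect.c_mmol_m3, logspace=logspace)
        rows.append(SensitivityRow(label=label, p_net_umol=p_net, kbar_m_d=kbar, stats=st))
    return rows


@dataclass
class UpscalingFit:
    slope: float
    intercept: float
    r2: float
    n: int


def upscaling_regression(records) -> UpscalingFit:
    """OLS of the specific net production rate on the trophic-light predictor.

    ``records`` is an iterable of dicts (or a DataFrame) with keys
    ``p_net`` (umol m-3 d-1), ``c_ch4`` (mmol m-3), ``chla`` (mg m-3),
    ``lc`` (-) and ``z_secchi`` (m). The response is the specific rate
    P_net / C_CH4 (d-1); the predictor is Chla * LC * Z_s.
    """
    recs = list(records.to_dict("records")) if hasattr(records, "to_dict") else list(records)
    if len(recs) < 3:
        raise ValueError("need at least 3 campaign records")
    y = np.array([r["p_net"] * 1e-3 / r["c_ch4"] for r in recs])  # d-1
    x = np.array([r["chla"] * r["lc"] * r["z_secchi"] for r in recs])
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in the predictor")
    fit = stats.linregress(x, y)
    return UpscalingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(recs),
    )
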