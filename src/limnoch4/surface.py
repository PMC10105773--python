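"""Floating-chamber surface fluxes, chamber-derived gas-transfer velocities,
and model-vs-measurement agreement statistics.

A deployment is accepted when the chamber headspace CH4 rises linearly over
the fit window (default first 5 min, R2 > 0.97); the slope is converted to a
flux with the ideal gas law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import R_GAS, SECONDS_PER_DAY
from .gas import k600_to_kgas, kgas_to_k600


@dataclass
class ChamberDeployment:
    """One floating-chamber time series (nominally 1 Hz ppm CH4)."""

    time_s: np.ndarray
    ppm: np.ndarray
    volume_m3: float  # chamber headspace volume
    area_m2: float  # water footprint
    t_a: float = 293.15  # K
    p_atm: float = 101325.0  # Pa
    c_w: float | None = None  # dissolved CH4 under the chamber, mmol m-3
    c_eq: float | None = None  # air-equilibrium CH4, mmol m-3
    station: str | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.time_s.size != self.ppm.size:
            raise ValueError("time and ppm series differ in length")
        if self.time_s.size < 30:
            raise ValueError("chamber series needs >= 30 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.time_s[-1] - self.time_s[0] < 120.0:
            raise ValueError("chamber deployment shorter than 120 s")


@dataclass
class ChamberFluxResult:
    flux: float | None  # mmol m-2 d-1; None when rejected
    slope_ppm_s: float
    r2: float | None
    accepted: bool
    flag: str | None = None
    n_used: int = 0


def chamber_flux(
    dep: ChamberDeployment,
    window_s: float = 300.0,
    r2_min: float = 0.97,
    settle_s: float = 10.0,
) -> ChamberFluxResult:
    """OLS slope of the chamber curve over the fit window, as a flux.

    The first ``settle_s`` seconds are skipped (placement artifact). The
    slope s (ppm s-1) converts to F_a = s*1e-6 * p_atm*V/(R*T_a*A) mol
    m-2 s-1, reported in mmol m-2 d-1. Deployments with fit R2 below
    ``r2_min`` (or a flat series, where R2 is undefined) are rejected.
    """
    if window_s < 60.0:
        raise ValueError("fit window must be at least 60 s")
    t0 = dep.time_s[0] + settle_s
    mask = (dep.time_s >= t0) & (dep.time_s <= t0 + window_s)
    t = dep.time_s[mask]
    y = dep.ppm[mask]
    if t.size < 10:
        raise ValueError("fit window contains fewer than 10 samples")
    if np.ptp(y) == 0.0:
        return ChamberFluxResult(None, 0.0, None, False, flag="flat-series", n_used=t.size)
    fit = stats.linregress(t, y)
    r2 = fit.rvalue**2
    slope = fit.slope
    flux = slope * 1e-6 * dep.p_atm * dep.volume_m3 / (R_GAS * dep.t_a * dep.area_m2)
    flux *= SECONDS_PER_DAY * 1e3  # mol m-2 s-1 -> mmol m-2 d-1
    if r2 < r2_min:
        return ChamberFluxResult(None, slope, r2, False, flag="nonlinear", n_used=t.size)
    return ChamberFluxResult(flux, slope, r2, True, n_used=t.size)


@dataclass
class ChamberK:
    k_ch4: float  # m d-1
    k600: float  # cm h-1
    flag: str | None = None


def chamber_k(
    f_a: float,
    c_w: float,
    c_eq: float,
    sc: float,
    u10: float,
    eps: float = 1e-9,
) -> ChamberK:
    """Chamber-based transfer velocity from Fick's law: k = F_a / (C_w - C_eq).

    ``f_a`` in mmol m-2 d-1 and concentrations in mmol m-3 give k in m d-1;
    the chamber-equivalent k600 inverts the Schmidt scaling at the ambient
    wind speed.
    """
    dc = c_w - c_eq
    if abs(dc) < eps:
        raise ValueError("C_w - C_eq below epsilon: transfer velocity undefined")
    k = f_a / dc
    flag = "negative-k" if k < 0 else None
    return ChamberK(k_ch4=k, k600=kgas_to_k600(k, sc, u10), flag=flag)


def surface_flux_from_k(k_ch4: float, c_w: float, c_eq: float) -> float:
    """F_a = k_CH4 * (C_w - C_eq); the forward form of Fick's law at the AWI."""
    return k_ch4 * (c_w - c_eq)


@dataclass
class FitStats:
    """Agreement between a predicted and an observed series."""

    rmse: float
    r2: float
    mnb_pct: float
    n: int
    logspace: bool = False


def compare_models(pred, obs, logspace: bool = False) -> FitStats:
    """RMSE, squared Pearson correlation, and mean normalized bias (percent).

    With ``logspace`` both series are log10-transformed first (the convention
    for comparing concentrations across lakes whose magnitudes differ by
    orders of magnitude); zero or negative values are then rejected with the
    offending indices listed.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.size != o.size or p.size < 2:
        raise ValueError("series must have equal length >= 2")
    if logspace:
        bad = np.nonzero((p <= 0) | (o <= 0))[0]
        if bad.size:
            raise ValueError(f"non-positive values at indices {bad.tolist()} in logspace mode")
        p = np.log10(p)
        o = np.log10(o)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if np.ptp(p) == 0.0 or np.ptp(o) == 0.0:
        r2 = 1.0 if rmse == 0.0 else 0.0
    else:
        r2 = float(stats.pearsonr(p, o).statistic ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mnb = float(100.0 * np.mean((p - o) / o)) if np.all(o != 0) else float("nan")
    return FitStats(rmse=rmse, r2=r2, mnb_pct=mnb, n=p.size, logspace=logspace)
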