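"""Gas-exchange physics: CH4 solubility, Schmidt-number scaling, wind-based
k600 parameterizations, and the headspace back-calculation for dissolved CH4.

Solubility follows the Wiesenburg & Guinasso moist-air equilibrium fit for
methane in fresh water (salinity terms dropped); the Henry solubility
``H_cp`` (mol m-3 Pa-1) is derived from it so that equilibrium
concentrations scale linearly with the local, altitude-corrected partial
pressure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CM_PER_HOUR_TO_M_PER_DAY,
    P_STANDARD,
    R_GAS,
    T_KELVIN,
    U10_SCHMIDT_SWITCH,
    X_CH4_ATM,
    barometric_pressure,
    schmidt_ch4,
)

log = logging.getLogger(__name__)

# Wiesenburg & Guinasso atmospheric-equilibrium coefficients for CH4
# (concentration branch, nmol L-1).
_WG_A = (-415.2807, 596.8104, 379.2599, -62.0757)


def wg_equilibrium_nmol(temp_c, x_ch4=X_CH4_ATM):
    """Atmospheric-equilibrium CH4 (nmol L-1) in fresh water at 1 atm.

    ``x_ch4`` is the atmospheric mole fraction (default 1.9 ppm).
    """
    t_k = np.asarray(temp_c, dtype=float) + T_KELVIN
    a1, a2, a3, a4 = _WG_A
    ln_c = np.log(x_ch4) + a1 + a2 * (100.0 / t_k) + a3 * np.log(t_k / 100.0) + a4 * (t_k / 100.0)
    return np.exp(ln_c)


def henry_cp_ch4(temp_c):
    """Henry solubility H_cp of CH4 (mol m-3 Pa-1) at water temperature.

    Derived from the solubility fit: H_cp = C_eq(1 atm) / pCH4(1 atm), so it
    is independent of the mixing ratio used internally.
    """
    c_nmol = wg_equilibrium_nmol(temp_c, X_CH4_ATM)  # nmol L-1 == umol m-3
    return c_nmol * 1e-6 / (X_CH4_ATM * P_STANDARD)


@dataclass
class GasConditions:
    """Ambient conditions controlling CH4 air-water equilibrium.

    Parameters not supplied are derived: ``p_atm`` from ``altitude_m`` via the
    barometric formula, ``pch4_atm`` from the atmospheric mixing ratio, and
    ``h_cp``/``sc`` from the water temperature.
    """

    t_w: float  # water temperature, degC
    t_a: float = 288.15  # air temperature, K
    altitude_m: float = 0.0
    p_atm: float | None = None  # Pa; barometric default from altitude
    x_ch4_atm: float = X_CH4_ATM  # atmospheric mole fraction
    pch4_atm: float = field(init=False)
    h_cp: float = field(init=False)  # mol m-3 Pa-1
    sc: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_w <= 40.0:
            warnings.warn(f"water temperature {self.t_w} degC outside 0-40 degC fit range")
        if self.p_atm is None:
            self.p_atm = barometric_pressure(self.altitude_m)
        self.pch4_atm = self.x_ch4_atm * self.p_atm
        self.h_cp = float(henry_cp_ch4(self.t_w))
        self.sc = float(schmidt_ch4(self.t_w))


def equilibrium_concentration(cond: GasConditions) -> float:
    """Air-equilibrium dissolved CH4, C_eq = H_cp * pCH4_atm (mmol m-3)."""
    return cond.h_cp * cond.pch4_atm * 1e3  # mol m-3 -> mmol m-3


@dataclass
class HeadspaceSample:
    """One headspace equilibration (bottle shaken until gas-water balance)."""

    x_meas_ppm: float  # measured headspace mixing ratio after equilibration
    t_equil_c: float  # equilibration temperature, degC
    x_amb_ppm: float = X_CH4_ATM * 1e6  # ambient air used to fill headspace
    v_air_ml: float = 500.0
    v_water_ml: float = 500.0
    p_atm: float = P_STANDARD
    t_a: float = 293.15  # gas-phase temperature for the mole count, K

    def __post_init__(self) -> None:
        if self.v_air_ml <= 0 or self.v_water_ml <= 0:
            raise ValueError("headspace and water volumes must be positive")


def headspace_backcalc(s: HeadspaceSample) -> float:
    """Dissolved CH4 of the original water sample (mmol m-3).

    Total CH4 after equilibration (headspace moles + water-phase moles at
    Henry equilibrium with the measured mixing ratio) minus the CH4 carried in
    with the ambient fill gas, divided by the water volume.
    """
    v_air = s.v_air_ml * 1e-6  # m3
    v_water = s.v_water_ml * 1e-6
    h_cp = float(henry_cp_ch4(s.t_equil_c))
    p_meas = s.x_meas_ppm * 1e-6 * s.p_atm
    p_amb = s.x_amb_ppm * 1e-6 * s.p_atm
    n_gas = p_meas * v_air / (R_GAS * s.t_a)  # mol
    n_aq = h_cp * p_meas * v_water
    n_intro = p_amb * v_air / (R_GAS * s.t_a)
    c_w = (n_gas + n_aq - n_intro) / v_water * 1e3  # mmol m-3
    if c_w < 0:
        warnings.warn("headspace back-calculation negative; clipped to 0 (blank contamination)")
        return 0.0
    return c_w


# -- k600 wind parameterizations --------------------------------------------

K600_MODEL_NAMES = ("CC98", "MA10-NB", "MA10-MB", "MA10-PB", "VP13", "chamber-mean")


@dataclass
class K600Model:
    """A named gas-transfer-velocity parameterization evaluated at U10.

    ``area_km2`` is the lake surface area (VP13 only); ``k600_chamber`` backs
    the 'chamber-mean' pseudo-model (measured mean, cm h-1).
    """

    name: str
    u10: float = 0.0
    area_km2: float | None = None
    k600_chamber: float | None = None

    def __post_init__(self) -> None:
        if self.name not in K600_MODEL_NAMES:
            raise ValueError(f"unknown k600 model {self.name!r}; choose from {K600_MODEL_NAMES}")
        if self.u10 < 0:
            raise ValueError("wind speed must be non-negative")


def k600_evaluate(model: K600Model) -> float:
    """k600 (cm h-1) for the named parameterization.

    Negative evaluations (MA10-PB at low wind) are clipped to zero and
    logged: a piston velocity cannot be negative.
    """
    u = model.u10
    if model.name == "CC98":
        k = 2.07 + 0.215 * u**1.7
    elif model.name == "MA10-NB":
        k = 2.045 * u + 2.0
    elif model.name == "MA10-MB":
        k = 2.25 * u + 0.16
    elif model.name == "MA10-PB":
        k = 1.75 * u - 0.15
    elif model.name == "VP13":
        if model.area_km2 is None or model.area_km2 <= 0:
            raise ValueError("VP13 requires the lake surface area in km2")
        k = 2.51 + 1.48 * u + 0.39 * u * np.log10(model.area_km2)
    else:  # chamber-mean
        if model.k600_chamber is None:
            raise ValueError("chamber-mean model requires the measured k600")
        k = model.k600_chamber
    if k < 0:
        log.info("k600 %s evaluated negative (%.3f cm h-1) at U10=%.2f; clipped to 0", model.name, k, u)
        k = 0.0
    return float(k)


def schmidt_exponent(u10: float) -> float:
    """Schmidt exponent n: 2/3 below the 3.7 m s-1 wind threshold, 1/2 above."""
    return 2.0 / 3.0 if u10 < U10_SCHMIDT_SWITCH else 0.5


def k600_to_kgas(k600_cm_h: float, sc: float, u10: float) -> float:
    """Convert k600 (cm h-1) to k_CH4 (m d-1) via (600/Sc)^n scaling."""
    if sc <= 0:
        raise ValueError("Schmidt number must be positive")
    n = schmidt_exponent(u10)
    return k600_cm_h * CM_PER_HOUR_TO_M_PER_DAY * (600.0 / sc) ** n


def kgas_to_k600(k_gas_m_d: float, sc: float, u10: float) -> float:
    """Inverse of :func:`k600_to_kgas`: k_CH4 (m d-1) back to k600 (cm h-1)."""
    if sc <= 0:
        raise ValueError("Schmidt number must be positive")
    n = schmidt_exponent(u10)
    return k_gas_m_d / CM_PER_HOUR_TO_M_PER_DAY * (sc / 600.0) ** n
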