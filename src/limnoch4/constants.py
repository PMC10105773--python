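"""Physical constants and small empirical fits shared across the package.

Internal unit policy: SI (mol, m, s, Pa, K) inside numerical kernels; the
public API reports fluxes in mmol m-2 d-1 and volumetric rates in
umol m-3 d-1, matching limnological convention.
"""

from __future__ import annotations

import numpy as np

R_GAS = 8.31446  # J mol-1 K-1
GRAVITY = 9.81  # m s-2
SECONDS_PER_DAY = 86400.0
CM_PER_HOUR_TO_M_PER_DAY = 0.24  # 1 cm h-1 = 0.24 m d-1
P_STANDARD = 101325.0  # Pa
T_KELVIN = 273.15

#: default atmospheric CH4 mixing ratio (mol fraction), ~1.9 ppm ambient
X_CH4_ATM = 1.9e-6

#: wind-speed threshold (m s-1) switching the Schmidt exponent 2/3 -> 1/2
U10_SCHMIDT_SWITCH = 3.7


def schmidt_ch4(temp_c):
    """Schmidt number of CH4 in fresh water (Wanninkhof-type polynomial).

    Valid 0-40 degC; monotonically decreasing with temperature.
    """
    t = np.asarray(temp_c, dtype=float)
    return 1909.4 - 120.78 * t + 3.7676 * t**2 - 0.047152 * t**3


def water_density(temp_c):
    """Fresh-water density (kg m-3) from temperature only.

    Polynomial fit adequate for dilute alpine lakes (conductivity ignored).
    """
    t = np.asarray(temp_c, dtype=float)
    return (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )


def barometric_pressure(altitude_m: float, temp_c: float = 10.0) -> float:
    """Site air pressure (Pa) from altitude via the barometric formula."""
    t_k = temp_c + T_KELVIN
    scale = R_GAS * t_k / (0.02896 * GRAVITY)
    return P_STANDARD * float(np.exp(-altitude_m / scale))


# Henry solubility H_cp (mol m-3 Pa-1) at 298.15 K and van 't Hoff temperature
# dependence d(ln H)/d(1/T) for the gases carried by the bubble model.
HENRY_CP_298 = {"CH4": 1.4e-5, "CO2": 3.3e-4, "O2": 1.3e-5, "N2": 6.4e-6}
HENRY_VANT_HOFF = {"CH4": 1750.0, "CO2": 2400.0, "O2": 1500.0, "N2": 1300.0}

# Molecular diffusivities in water at 25 degC (m2 s-1), with a mild linear
# temperature correction applied in `molecular_diffusivity`.
DIFFUSIVITY_298 = {"CH4": 1.84e-9, "CO2": 1.92e-9, "O2": 2.20e-9, "N2": 2.00e-9}


def henry_cp(gas: str, temp_c) -> float:
    """Henry solubility H_cp (mol m-3 Pa-1) of `gas` at water temperature."""
    t_k = np.asarray(temp_c, dtype=float) + T_KELVIN
    return HENRY_CP_298[gas] * np.exp(HENRY_VANT_HOFF[gas] * (1.0 / t_k - 1.0 / 298.15))


def molecular_diffusivity(gas: str, temp_c) -> float:
    """Molecular diffusivity (m2 s-1) of `gas` in water, ~2.5 %/degC slope."""
    t = np.asarray(temp_c, dtype=float)
    return DIFFUSIVITY_298[gas] * (1.0 + 0.025 * (t - 25.0))
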