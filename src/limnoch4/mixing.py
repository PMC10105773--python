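"""Turbulent vertical diffusivity from Thorpe-scale analysis and the
vertical diffusive CH4 flux across the SML base.

Sorting an unstable temperature cast into its monotone (stable) arrangement
yields Thorpe displacements; the largest displacement inside the analysis
layer sets L_max, the Thorpe scale L_T = (sqrt(2)/7.3) L_max, and the
Ozmidov-style diffusivity K_z = gamma_mix * L_T^2 * N with N the buoyancy
frequency of the sorted profile (temperature-only equation of state;
adequate for dilute alpine lakes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GRAVITY, water_density
from .geometry import TemperatureProfile

THORPE_FACTOR = np.sqrt(2.0) / 7.3
#: diffusivity reported when no overturn is detected (near-molecular), m2 s-1
KZ_FLOOR = 1e-7


@dataclass
class DiffusivityEstimate:
    k_z: float  # m2 s-1
    n_buoy: float  # buoyancy frequency, s-1
    l_max: float  # maximum Thorpe displacement, m
    l_thorpe: float  # m
    gamma_mix: float
    no_overturn: bool = False


def thorpe_displacements(depth_m: np.ndarray, temp_c: np.ndarray) -> np.ndarray:
    """Displacement of each sample under a stable (descending-T) resort.

    Positive displacement means the parcel must move downward to reach its
    stable position. A monotone profile gives all-zero displacements.
    """
    order = np.argsort(-temp_c, kind="stable")  # warm on top
    dest = np.empty_like(order)
    dest[order] = np.arange(order.size)  # stable position of each sample
    return depth_m[dest] - depth_m


def buoyancy_frequency(depth_m: np.ndarray, temp_sorted_c: np.ndarray) -> float:
    """Layer-mean N (s-1) from the sorted profile's density gradient."""
    rho = water_density(temp_sorted_c)
    drho_dz = np.polyfit(depth_m, rho, 1)[0]  # kg m-4, z positive down
    n2 = GRAVITY / np.mean(rho) * drho_dz  # stable: density increasing downward
    if n2 <= 0:
        raise ValueError("unstable mean stratification in the analysis layer (N^2 <= 0)")
    return float(np.sqrt(n2))


def thorpe_kz(
    profile: TemperatureProfile,
    layer: tuple[float, float],
    gamma_mix: float = 0.15,
    noise_c: float = 0.01,
    kz_floor: float = KZ_FLOOR,
) -> DiffusivityEstimate:
    """Thorpe-scale K_z within ``layer`` = (z_top, z_bottom) in metres.

    Displacements smaller than twice the noise-equivalent length (sensor
    noise ``noise_c`` divided by the layer-mean |dT/dz|) are zeroed. With no
    surviving overturn the floor diffusivity is returned, flagged.
    """
    z_top, z_bot = layer
    mask = (profile.depth_m >= z_top) & (profile.depth_m <= z_bot)
    z = profile.depth_m[mask]
    t = profile.temp_c[mask]
    if z.size < 10:
        raise ValueError("analysis layer holds fewer than 10 samples")
    raw_drho = np.polyfit(z, water_density(t), 1)[0]
    if raw_drho <= 0:
        raise ValueError("unstable mean stratification in the analysis layer (N^2 <= 0)")
    disp = thorpe_displacements(z, t)
    t_sorted = np.sort(t)[::-1]
    n_buoy = buoyancy_frequency(z, t_sorted)
    grad = abs(np.polyfit(z, t_sorted, 1)[0])
    if grad > 0 and noise_c > 0:
        disp = np.where(np.abs(disp) < 2.0 * noise_c / grad, 0.0, disp)
    l_max = float(np.max(np.abs(disp)))
    if l_max == 0.0:
        return DiffusivityEstimate(
            k_z=kz_floor, n_buoy=n_buoy, l_max=0.0, l_thorpe=0.0,
            gamma_mix=gamma_mix, no_overturn=True,
        )
    l_t = THORPE_FACTOR * l_max
    k_z = gamma_mix * l_t**2 * n_buoy
    return DiffusivityEstimate(
        k_z=float(k_z), n_buoy=n_buoy, l_max=l_max, l_thorpe=float(l_t),
        gamma_mix=gamma_mix, no_overturn=False,
    )


def fz_flux(k_z: float, depth_m, conc_mmol_m3) -> float:
    """Vertical diffusive CH4 flux across the SML base (mmol m-2 d-1).

    F_z = -K_z dC/dz with z positive downward; reported positive when CH4
    moves upward INTO the SML (concentration increasing with depth).
    """
    z = np.asarray(depth_m, dtype=float)
    c = np.asarray(conc_mmol_m3, dtype=float)
    if z.size < 2 or np.ptp(z) == 0.0:
        raise ValueError("need >= 2 distinct depths spanning the SML base")
    dcdz = np.polyfit(z, c, 1)[0]  # mmol m-4
    return float(k_z * dcdz * 86400.0)
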