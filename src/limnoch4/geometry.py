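"""Lake morphometry, mixed-layer detection, and the radial geometry used by
the 1-D lateral transport model.

The surface mixed layer (SML) base is the shallowest depth where the vertical
temperature gradient dT/dz (z positive downward) first drops below a
threshold, default -1 degC m-1. The 1-D model maps the lake onto a disk of
radius r_max = sqrt(A_a/pi); the littoral annulus (r >= r_s) thins linearly
from the mixed-layer depth to zero at the shore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt


class InvalidProfileError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class TemperatureProfile:
    """A CTD temperature cast, surface down."""

    depth_m: np.ndarray
    temp_c: np.ndarray
    station: str | None = None

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.depth_m.size < 3:
            raise InvalidProfileError("temperature profile needs at least 3 points")
        if self.depth_m.size != self.temp_c.size:
            raise InvalidProfileError("depth and temperature grids differ in length")
        if np.any(np.diff(self.depth_m) <= 0):
            raise InvalidProfileError("depths must be strictly increasing (surface down)")


@dataclass
class LakeMorphometry:
    """Planar areas and SML volume of a lake.

    ``hypsograph`` maps depth (m) to planar area (m2), non-increasing with
    depth; when both hypsograph and ``v_sml`` are given they must agree to 5 %
    on the SML volume.
    """

    a_surface: float  # A_a, lake surface area, m2
    a_sediment: float  # A_s, littoral (SML-exposed) sediment area, m2
    a_sml_base: float  # A_z, planar area at the SML base, m2
    v_sml: float  # SML volume, m3
    hypsograph: tuple[np.ndarray, np.ndarray] | None = None  # (depth_m, area_m2)
    altitude_m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a_surface", "a_sediment", "a_sml_base", "v_sml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a_sml_base > self.a_surface or self.a_sediment > self.a_surface:
            raise ValueError("A_z and A_s cannot exceed the surface area A_a")
        if self.hypsograph is not None:
            z, a = (np.asarray(v, dtype=float) for v in self.hypsograph)
            if np.any(np.diff(z) <= 0) or np.any(np.diff(a) > 0):
                raise ValueError("hypsograph must be increasing in depth, non-increasing in area")
            self.hypsograph = (z, a)

    def hypsograph_volume(self, h_sml: float) -> float:
        """SML volume implied by the hypsograph, trapezoid-integrated to h_sml."""
        if self.hypsograph is None:
            raise ValueError("no hypsograph supplied")
        z, a = self.hypsograph
        zz = np.linspace(0.0, h_sml, 201)
        return float(np.trapezoid(np.interp(zz, z, a), zz))


@dataclass
class RadialGeometry:
    """Disk-equivalent geometry for the lateral transport model."""

    r_max: float  # center-to-shore radius, m
    r_s: float  # pelagic/littoral boundary radius, m
    h_sml: float  # mixed-layer depth, m

    def h_of_r(self, r):
        """SML thickness at radius r: flat in the pelagic, linear ramp to 0 at shore."""
        r = np.asarray(r, dtype=float)
        ramp = self.h_sml * (self.r_max - r) / (self.r_max - self.r_s)
        return np.where(r < self.r_s, self.h_sml, np.clip(ramp, 0.0, self.h_sml))


@dataclass
class SmlDepth:
    depth_m: float
    unstratified: bool = False


def detect_sml_depth(
    profile: TemperatureProfile,
    threshold: float = -1.0,
    smooth: bool = True,
) -> SmlDepth:
    """Mixed-layer depth: shallowest depth where dT/dz < threshold.

    The gradient is a centered finite difference on interior points (one-sided
    at the ends), with optional 3-point median pre-smoothing to suppress
    sensor spikes. A profile whose gradient never crosses the threshold is
    returned as unstratified at its deepest depth.
    """
    if threshold >= 0:
        raise ValueError("threshold must be negative (temperature decreasing downward)")
    z = profile.depth_m
    t = profile.temp_c
    if smooth and t.size >= 3:
        t = medfilt(t, 3)
    grad = np.gradient(t, z)
    below = np.nonzero(grad < threshold)[0]
    if below.size == 0:
        return SmlDepth(float(z[-1]), unstratified=True)
    return SmlDepth(float(z[below[0]]), unstratified=False)


def radial_geometry(morph: LakeMorphometry, h_sml: float) -> RadialGeometry:
    """Disk radii from planar areas: r_max = sqrt(A_a/pi), r_s = sqrt((A_a-A_s)/pi)."""
    if morph.a_sediment >= morph.a_surface:
        raise DegenerateGeometryError("littoral sediment area A_s must be < lake area A_a")
    r_max = float(np.sqrt(morph.a_surface / np.pi))
    r_s = float(np.sqrt((morph.a_surface - morph.a_sediment) / np.pi))
    return RadialGeometry(r_max=r_max, r_s=r_s, h_sml=h_sml)


def sml_volume_of_revolution(geom: RadialGeometry, n: int = 20001) -> float:
    """SML volume implied by H(r): 2*pi * int r H(r) dr (quadrature)."""
    r = np.linspace(0.0, geom.r_max, n)
    return float(2.0 * np.pi * np.trapezoid(r * geom.h_of_r(r), r))


@dataclass
class LightClimate:
    """Mean SML light-exposure proxy LC = 2.5 * Z_s / H_SML (dimensionless)."""

    z_secchi: float
    h_sml: float
    chla: float | None = None  # mg m-3, carried for the upscaling regression
    lc: float = field(init=False)

    def __post_init__(self) -> None:
        self.lc = light_climate(self.z_secchi, self.h_sml)


def light_climate(z_secchi: float, h_sml: float) -> float:
    """LC = 2.5 * Z_s / H_SML; both arguments in metres, both positive."""
    if z_secchi <= 0 or h_sml <= 0:
        raise ValueError("Secchi depth and SML depth must be positive")
    return 2.5 * z_secchi / h_sml
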