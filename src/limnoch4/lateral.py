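"""Radially symmetric 1-D lateral transport model of SML methane.

The steady balance on a disk (r = 0 at the lake center, r_max at the shore)
reads, per unit SML volume:

    0 = K_H (1/(H r)) d/dr (H r dC/dr)          horizontal dispersion
      + (K_z / H) (C_hyp - C) / dz              exchange with the hypolimnion
      - (kbar / H) (C - C_eq)                   exchange with the atmosphere
      + F_s(r) / H                              littoral sediment source
      + R_dis(r) + P_net                        bubble dissolution, net production

with F_s(r) nonzero only in the littoral annulus r >= r_s, SML thickness
H(r) ramping linearly to zero at the shore, and zero-flux conditions at both
radial boundaries. The equation is linear in C, so the steady state is one
sparse (tridiagonal) solve; P_net enters affinely, which reduces the
transect fit to one-parameter linear least squares.

Internal working units: metres, days, mmol m-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .constants import SECONDS_PER_DAY
from .geometry import RadialGeometry

#: floor on the SML thickness in the shore cell, avoids the H -> 0 singularity
H_FLOOR_M = 0.05


@dataclass
class Transect:
    """Folded shore-to-center surface CH4 stations."""

    r_m: np.ndarray  # radial coordinate of each station, 0 = center
    c_mmol_m3: np.ndarray
    d13c: np.ndarray | None = None  # carried only, never modeled

    def __post_init__(self) -> None:
        self.r_m = np.asarray(self.r_m, dtype=float)
        self.c_mmol_m3 = np.asarray(self.c_mmol_m3, dtype=float)
        if self.r_m.size < 5:
            raise ValueError("a transect needs at least 5 stations")
        if np.any(self.r_m < 0):
            raise ValueError("radial coordinates must be non-negative")


def fold_transect(distance_m, r_max: float) -> np.ndarray:
    """Map shore-to-shore transect distances onto radii.

    A station at distance d along a diameter of length 2 r_max lies
    r = r_max - (distance to the nearest shore) from the center.
    """
    d = np.asarray(distance_m, dtype=float)
    nearest_shore = np.minimum(d, 2.0 * r_max - d)
    return r_max - nearest_shore


@dataclass
class RadialField:
    """Cell-centered steady solution of the lateral model."""

    r_m: np.ndarray
    c_mmol_m3: np.ndarray
    h_m: np.ndarray
    negative_c: float = 0.0  # most negative concentration, 0 if none

    def interp(self, r):
        return np.interp(r, self.r_m, self.c_mmol_m3)


@dataclass
class LateralInputs:
    """Boundary conditions of the lateral model (reported units)."""

    k_h_m2_d: float  # horizontal dispersion
    k_z_m2_s: float  # vertical diffusivity at the SML base
    kbar_m_d: float  # air-water transfer velocity of CH4
    c_hyp: float  # CH4 1 m below the SML base, mmol m-3
    c_eq: float  # air-equilibrium CH4, mmol m-3
    f_s: float  # littoral sediment flux, mmol m-2 d-1
    r_dis_umol: float = 0.0  # SML bubble dissolution, umol m-3 d-1
    dz_m: float = 1.0


def _grid(geom: RadialGeometry, n_cells: int):
    dr = geom.r_max / n_cells
    r_c = (np.arange(n_cells) + 0.5) * dr
    r_f = np.arange(n_cells + 1) * dr
    h_c = np.maximum(geom.h_of_r(r_c), 0.0)
    h_c[-1] = max(h_c[-1], H_FLOOR_M)
    return dr, r_c, r_f, h_c


def lateral_steady_solve(
    geom: RadialGeometry,
    inputs: LateralInputs,
    p_net_umol: float,
    n_cells: int = 200,
) -> RadialField:
    """Direct steady solve of the lateral model (mmol m-3 on cell centers)."""
    if n_cells < 50:
        raise ValueError("use at least 50 radial cells")
    dr, r_c, r_f, h_c = _grid(geom, n_cells)
    k_z_d = inputs.k_z_m2_s * SECONDS_PER_DAY
    p_net = p_net_umol * 1e-3  # mmol m-3 d-1
    r_dis = inputs.r_dis_umol * 1e-3

    # harmonic-mean face thickness; interior faces only (zero-flux boundaries)
    h_f = 2.0 * h_c[:-1] * h_c[1:] / (h_c[:-1] + h_c[1:])

    main = np.zeros(n_cells)
    lower = np.zeros(n_cells - 1)
    upper = np.zeros(n_cells - 1)
    rhs = np.zeros(n_cells)

    disp = inputs.k_h_m2_d * h_f * r_f[1:-1] / dr**2  # face conductances * H r
    for j in range(n_cells):
        scale = 1.0 / (h_c[j] * r_c[j])
        if j > 0:
            d = disp[j - 1] * scale
            main[j] -= d
            lower[j - 1] += d
        if j < n_cells - 1:
            d = disp[j] * scale
            main[j] -= d
            upper[j] += d

    vert = k_z_d / (h_c * inputs.dz_m)
    surf = inputs.kbar_m_d / h_c
    f_s_r = np.where(r_c >= geom.r_s, inputs.f_s, 0.0)

    main -= vert + surf
    rhs -= vert * inputs.c_hyp + surf * inputs.c_eq + f_s_r / h_c + r_dis + p_net

    if np.all(vert == 0.0) and np.all(surf == 0.0):
        raise ValueError("singular steady problem: no vertical or surface exchange")

    ab = np.zeros((3, n_cells))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    c = solve_banded((1, 1), ab, rhs)
    neg = float(min(c.min(), 0.0))
    return RadialField(r_m=r_c, c_mmol_m3=c, h_m=h_c, negative_c=neg)


def lateral_transient(
    geom: RadialGeometry,
    inputs: LateralInputs,
    p_net_umol: float,
    c0_mmol_m3: float,
    t_end_d: float,
    dt_d: float = 0.1,
    n_cells: int = 200,
) -> RadialField:
    """Implicit-Euler time stepping of the same balance (cross-validation mode).

    Starts from a uniform concentration and integrates to ``t_end_d``; for
    long horizons the result converges to :func:`lateral_steady_solve`.
    """
    dr, r_c, r_f, h_c = _grid(geom, n_cells)
    k_z_d = inputs.k_z_m2_s * SECONDS_PER_DAY
    p_net = p_net_umol * 1e-3
    r_dis = inputs.r_dis_umol * 1e-3
    h_f = 2.0 * h_c[:-1] * h_c[1:] / (h_c[:-1] + h_c[1:])
    disp = inputs.k_h_m2_d * h_f * r_f[1:-1] / dr**2

    n = n_cells
    a_mat = np.zeros((n, n))
    for j in range(n):
        scale = 1.0 / (h_c[j] * r_c[j])
        if j > 0:
            d = disp[j - 1] * scale
            a_mat[j, j] -= d
            a_mat[j, j - 1] += d
        if j < n - 1:
            d = disp[j] * scale
            a_mat[j, j] -= d
            a_mat[j, j + 1] += d
    vert = k_z_d / (h_c * inputs.dz_m)
    surf = inputs.kbar_m_d / h_c
    a_mat[np.diag_indices(n)] -= vert + surf
    const = vert * inputs.c_hyp + surf * inputs.c_eq
    const += np.where(r_c >= geom.r_s, inputs.f_s, 0.0) / h_c + r_dis + p_net

    c = np.full(n, float(c0_mmol_m3))
    lhs = np.eye(n) - dt_d * a_mat
    n_steps = int(np.ceil(t_end_d / dt_d))
    for _ in range(n_steps):
        c = np.linalg.solve(lhs, c + dt_d * const)
    return RadialField(r_m=r_c, c_mmol_m3=c, h_m=h_c, negative_c=float(min(c.min(), 0.0)))


def implied_boundary_fluxes(
    geom: RadialGeometry,
    inputs: LateralInputs,
    field: RadialField,
    p_net_umol: float = 0.0,
) -> dict:
    """Area-integrated boundary exchanges of a steady radial field.

    Returns totals in mmol d-1 plus the equivalent mean fluxes: surface flux
    per unit lake area (F_a) and vertical flux per unit SML-base area (F_z,
    the pelagic disk pi r_s^2). ``residual`` is the volume-integrated budget
    imbalance relative to the largest term — at steady state it vanishes to
    solver tolerance.
    """
    r = field.r_m
    dr = r[1] - r[0]
    ring = 2.0 * np.pi * r * dr  # planar ring areas, sums to pi r_max^2
    vol = ring * field.h_m
    c = field.c_mmol_m3
    k_z_d = inputs.k_z_m2_s * SECONDS_PER_DAY
    f_a_total = float(np.sum(inputs.kbar_m_d * (c - inputs.c_eq) * ring))
    f_z_total = float(np.sum(k_z_d * (inputs.c_hyp - c) / inputs.dz_m * ring))
    f_s_total = float(np.sum(np.where(r >= geom.r_s, inputs.f_s, 0.0) * ring))
    r_dis_total = float(inputs.r_dis_umol * 1e-3 * np.sum(vol))
    p_net_total = float(p_net_umol * 1e-3 * np.sum(vol))
    a_surface = np.pi * geom.r_max**2
    a_base = np.pi * geom.r_s**2
    sources = f_s_total + f_z_total + r_dis_total + p_net_total
    scale = max(abs(f_a_total), abs(sources), 1e-30)
    return {
        "f_a_total": f_a_total,
        "f_z_total": f_z_total,
        "f_s_total": f_s_total,
        "r_dis_total": r_dis_total,
        "p_net_total": p_net_total,
        "f_a_mean": f_a_total / a_surface,
        "f_z_mean": f_z_total / a_base,
        "residual": (sources - f_a_total) / scale,
    }


@dataclass
class LateralFit:
    p_net_umol: float
    residuals: np.ndarray
    r2: float
    c_model: np.ndarray  # modeled concentration at the station radii
    c0: RadialField = field(repr=False, default=None)
    sensitivity: RadialField = field(repr=False, default=None)


def pnet_lateral_fit(
    geom: RadialGeometry,
    inputs: LateralInputs,
    transect: Transect,
    n_cells: int = 200,
) -> LateralFit:
    """Least-squares P_net from a surface transect.

    The steady solution is affine in P_net, C(r; P) = C0(r) + P * S(r), so
    the optimal P_net has the closed form sum(S (C_obs - C0)) / sum(S^2);
    unbounded, negative values allowed (net oxidation).
    """
    if np.ptp(transect.r_m) == 0.0:
        raise ValueError("degenerate transect: all stations at one radius")
    base = lateral_steady_solve(geom, inputs, 0.0, n_cells)
    bumped = lateral_steady_solve(geom, inputs, 1.0, n_cells)
    sens = RadialField(
        r_m=base.r_m, c_mmol_m3=bumped.c_mmol_m3 - base.c_mmol_m3, h_m=base.h_m
    )
    s = sens.interp(transect.r_m)
    c0 = base.interp(transect.r_m)
    denom = float(np.sum(s**2))
    if denom == 0.0:
        raise ValueError("transect insensitive to P_net (zero sensitivity)")
    p_net = float(np.sum(s * (transect.c_mmol_m3 - c0)) / denom)
    c_model = c0 + p_net * s
    resid = transect.c_mmol_m3 - c_model
    ss_tot = float(np.sum((transect.c_mmol_m3 - transect.c_mmol_m3.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return LateralFit(
        p_net_umol=p_net, residuals=resid, r2=r2, c_model=c_model, c0=base, sensitivity=sens
    )
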