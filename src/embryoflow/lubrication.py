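"""Long-wavelength (lubrication) flow in an elongated axisymmetric cell.

When axial length scales are much larger than radial ones (|R'(z)| << 1 for
cell radius R(z)), the cortically driven Stokes flow reduces to locally
parabolic pipe flow with zero net flux through every cross-section:

    u_z(r, z) = U(z) * [2 (r/R)^2 - 1],
    u_r(r, z) = (1/2) U'(z) r [1 - (r/R)^2] + U(z) R'(z) (r/R)^3,

where ``U(z)`` is the axial component of the cortical slip velocity at the
wall.  The solution satisfies the wall slip ``u_z(R, z) = U``, the axial
return flow ``u_z(0, z) = -U``, exact no-penetration on the wall and zero
cross-sectional mass flux, all by construction.  It applies to any elongated
shape, not just spheroids; for a spheroidal cell it agrees with the exact
series solution of :mod:`embryoflow.stokes` to within a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import EmbryoGeometry
from .stokes import SeriesCoefficients, SlipProfile, velocity_rz

__all__ = [
    "RadiusProfile",
    "AxialSlip",
    "slip_to_axial",
    "spheroid_radius_profile",
    "LubricationFlowField",
    "compare_to_exact",
]

_POLE_EPS = 1e-6  # evaluation restricted to |z| <= (1 - eps) * bz


@dataclass(frozen=True)
class RadiusProfile:
    """Cell radius ``R(z)`` (um) on (-bz, bz) with optional analytic slope."""

    radius: Callable[[np.ndarray], np.ndarray]
    bz: float
    slope: Callable[[np.ndarray], np.ndarray] | None = None

    def d_radius(self, z, h: float = 1e-4):
        if self.slope is not None:
            return self.slope(np.asarray(z, dtype=float))
        z = np.asarray(z, dtype=float)
        return (self.radius(z + h) - self.radius(z - h)) / (2.0 * h)


@dataclass(frozen=True)
class AxialSlip:
    """Axial wall slip ``U(z)`` (um/s) with optional analytic derivative."""

    U: Callable[[np.ndarray], np.ndarray]
    bz: float
    dU: Callable[[np.ndarray], np.ndarray] | None = None

    def d_U(self, z, h: float = 1e-4):
        if self.dU is not None:
            return self.dU(np.asarray(z, dtype=float))
        z = np.asarray(z, dtype=float)
        return (self.U(z + h) - self.U(z - h)) / (2.0 * h)


def slip_to_axial(vs: SlipProfile | Callable, g: EmbryoGeometry) -> AxialSlip:
    """Project a tangential slip profile onto the z-direction.

    ``U(z) = (e_z . e_zeta)(tau0, z/bz) * v_s(z/bz)``; the projection factor
    ``tau0 sqrt(1 - zeta^2) / sqrt(tau0^2 - zeta^2)`` is retained exactly
    (it is 1 at the equator and decays to 0 at the poles).
    """
    vs_fun = vs if callable(vs) else vs.shape

    def U(z):
        zeta = np.clip(np.asarray(z, dtype=float) / g.bz, -1.0, 1.0)
        proj = g.tau0 * np.sqrt(1.0 - zeta**2) / np.sqrt(g.tau0**2 - zeta**2)
        return proj * np.asarray(vs_fun(zeta), dtype=float)

    return AxialSlip(U=U, bz=g.bz)


def spheroid_radius_profile(g: EmbryoGeometry) -> RadiusProfile:
    """``R(z) = bx sqrt(1 - (z/bz)^2)`` with its analytic slope."""

    def radius(z):
        return g.bx * np.sqrt(np.clip(1.0 - (np.asarray(z) / g.bz) ** 2, 0.0, None))

    def slope(z):
        z = np.asarray(z, dtype=float)
        s = np.clip(1.0 - (z / g.bz) ** 2, 1e-300, None)
        return -g.bx * z / (g.bz**2 * np.sqrt(s))

    return RadiusProfile(radius=radius, bz=g.bz, slope=slope)


class LubricationFlowField:
    """Long-wavelength flow field; same evaluation protocol as the exact one.

    Warns (once, at construction) if ``max |R'(z)|`` over the central bulk
    (|z| <= 0.7 bz) exceeds 0.5, i.e. when the geometry leaves the validity
    regime already away from the poles.  The pole caps of any closed shape
    have diverging slope and are excluded from evaluation anyway.
    """

    def __init__(self, axial_slip: AxialSlip, radius_profile: RadiusProfile,
                 geometry: EmbryoGeometry | None = None):
        self.axial = axial_slip
        self.rp = radius_profile
        self.geometry = geometry
        zg = np.linspace(-0.7 * radius_profile.bz, 0.7 * radius_profile.bz, 201)
        if np.max(np.abs(radius_profile.d_radius(zg))) > 0.5:
            import warnings

            warnings.warn("radius profile slope exceeds 0.5; outside the "
                          "long-wavelength validity regime", stacklevel=2)

    @classmethod
    def for_spheroid(cls, vs: SlipProfile | Callable, g: EmbryoGeometry) -> "LubricationFlowField":
        return cls(slip_to_axial(vs, g), spheroid_radius_profile(g), geometry=g)

    def velocity_rz(self, r, z):
        """``(u_r, u_z)`` (um/s) at meridional points ``0 <= r <= R(z)``."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        r, z = np.broadcast_arrays(r, z)
        bz = self.rp.bz
        z = np.clip(z, -(1.0 - _POLE_EPS) * bz, (1.0 - _POLE_EPS) * bz)
        R = np.asarray(self.rp.radius(z), dtype=float)
        if np.any(r > R * (1.0 + 1e-9)):
            raise ValueError("point(s) outside the cell: r > R(z)")
        x = r / R
        U = np.asarray(self.axial.U(z), dtype=float)
        dU = np.asarray(self.axial.d_U(z), dtype=float)
        dR = np.asarray(self.rp.d_radius(z), dtype=float)
        u_z = U * (2.0 * x**2 - 1.0)
        u_r = 0.5 * dU * r * (1.0 - x**2) + U * dR * x**3
        return u_r, u_z

    def velocity_xyz(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rr = np.hypot(pts[:, 0], pts[:, 1])
        u_r, u_z = self.velocity_rz(rr, pts[:, 2])
        with np.errstate(invalid="ignore", divide="ignore"):
            cosp = np.where(rr > 0, pts[:, 0] / rr, 0.0)
            sinp = np.where(rr > 0, pts[:, 1] / rr, 0.0)
        return np.column_stack([u_r * cosp, u_r * sinp, u_z])

    def streamfunction(self, r, z):
        """Closed-form Stokes streamfunction of the parabolic profile.

        ``psi = -U(z) r^2 / 2 * (1 - (r/R)^2)`` with the convention
        ``u_z = (1/r) dpsi/dr``; used for vortex counting.
        """
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        R = np.asarray(self.rp.radius(z), dtype=float)
        U = np.asarray(self.axial.U(z), dtype=float)
        return -U * r**2 / 2.0 * (1.0 - (r / R) ** 2)

    def count_vortices(self, grid_shape: tuple[int, int] = (60, 160)) -> int:
        """Meridional vortex count from sign regions of the streamfunction."""
        from .stokes import _count_sign_regions

        bz = self.rp.bz
        nr, nz = grid_shape
        zg = np.linspace(-0.97 * bz, 0.97 * bz, nz)
        psi = np.empty((nr, nz))
        for j, zz in enumerate(zg):
            R = float(self.rp.radius(zz))
            rg = np.linspace(0.02 * R, 0.95 * R, nr)
            psi[:, j] = self.streamfunction(rg, np.full_like(rg, zz))
        return _count_sign_regions(psi)


def compare_to_exact(
    vs: SlipProfile | Callable,
    g: EmbryoGeometry,
    coeffs: SeriesCoefficients | None = None,
    n_z: int = 160,
    n_r: int = 40,
    pole_cap: float = 0.01,
    return_fields: bool = False,
):
    """Normalized error of the lubrication field against the exact series.

    Evaluates both solvers on an interior grid excluding a pole cap of
    ``pole_cap * bz`` and returns ``(max_err_uz, max_err_ur)`` where each is
    ``max |u_i_exact - u_i_lub| / max |u_i_exact|`` (the normalization by the
    global maximum of each component matches how the error field of the two
    solutions is usually reported).
    """
    from .stokes import solve_slip_flow

    if coeffs is None:
        coeffs = solve_slip_flow(vs, g)
    lub = LubricationFlowField.for_spheroid(vs, g)
    zg = np.linspace(-(1.0 - pole_cap) * g.bz, (1.0 - pole_cap) * g.bz, n_z)
    rows = []
    for zz in zg:
        R = float(g.radius_at(zz))
        rr = np.linspace(0.0, R * (1.0 - 1e-9), n_r)
        zcol = np.full_like(rr, zz)
        ur_e, uz_e = velocity_rz(coeffs, rr, zcol)
        ur_l, uz_l = lub.velocity_rz(rr, zcol)
        rows.append((rr, zcol, ur_e, uz_e, ur_l, uz_l))
    ur_e, uz_e, ur_l, uz_l = (np.concatenate([row[i] for row in rows]) for i in (2, 3, 4, 5))
    max_uz = np.max(np.abs(uz_e))
    max_ur = np.max(np.abs(ur_e))
    err_uz = float(np.max(np.abs(uz_e - uz_l)) / max_uz) if max_uz > 0 else 0.0
    err_ur = float(np.max(np.abs(ur_e - ur_l)) / max_ur) if max_ur > 0 else 0.0
    if return_fields:
        r_all = np.concatenate([row[0] for row in rows])
        z_all = np.concatenate([row[1] for row in rows])
        return err_uz, err_ur, {
            "r_um": r_all, "z_um": z_all,
            "err_uz": np.abs(uz_e - uz_l) / max_uz,
            "err_ux": np.abs(ur_e - ur_l) / max_ur,
        }
    return err_uz, err_ur
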