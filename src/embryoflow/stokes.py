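"""Exact interior Stokes flow in a prolate spheroid driven by boundary slip.

The axisymmetric incompressible Stokes flow inside the spheroid, driven by a
prescribed tangential slip velocity ``v_s(zeta) e_zeta`` on the boundary, is
written as a semiseparable Gegenbauer streamfunction series

    psi(tau, zeta) = sum_{n>=2} g_n(tau) G_n(zeta),

where each radial function is a finite combination of Gegenbauer functions,

    g_2 = F_2 G_2 + E_4 G_4,
    g_3 = F_3 G_3 + E_5 G_5,
    g_n = F_n G_n + E_{n+2} G_{n+2} + E_n G_{n-2}    (n >= 4).

Second-kind Gegenbauer functions are excluded by regularity on the axis, and
the lowest two radial modes by regularity on the focal segment.  The slip
profile is expanded in associated Legendre functions,

    v_s(zeta) = tau0 / sqrt(tau0^2 - zeta^2) * sum_{n>=1} B_n P_n^1(zeta),

and the boundary conditions close the series order by order:
impenetrability gives ``g_n(tau0) = 0`` and the prescribed slip gives
``g_n'(tau0) = tau0 c^2 n (n-1) B_{n-1}``.  Even and odd orders decouple into
two independent ladders of 2x2 linear solves.

The flow is linear in the slip amplitude, so all fields are computed for a
unit-amplitude profile and rescaled by the cortical amplitude V(t) at use
time (see :mod:`embryoflow.transport`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import ndimage

from .geometry import (
    EmbryoGeometry,
    assoc_legendre_P1,
    gegenbauer_G,
    gegenbauer_G_prime,
    gegenbauer_table,
    legendre_table,
    to_spheroidal,
)

__all__ = [
    "SlipProfile",
    "ModeCoefficients",
    "SeriesCoefficients",
    "compute_slip_coefficients",
    "solve_series",
    "solve_slip_flow",
    "streamfunction",
    "velocity_spheroidal",
    "velocity_rz",
    "StokesFlowField",
    "truncation_study",
    "count_vortices",
]

DEFAULT_NMAX = 14  # truncation order; higher orders give <0.1% changes


@dataclass(frozen=True)
class SlipProfile:
    """Tangential slip velocity on the boundary, positive along ``e_zeta``.

    ``shape`` maps zeta in [-1, 1] to the slip speed per unit amplitude;
    ``amplitude`` (um/s) scales it.  Physically sensible cortical profiles
    vanish at the poles (no sources or sinks of cortical material there); a
    profile that does not is accepted with a warning.
    """

    shape: Callable[[np.ndarray], np.ndarray]
    amplitude: float = 1.0
    name: str = "custom"

    def __post_init__(self):
        poles = np.abs(self(np.array([-1.0, 1.0])))
        scale = max(np.max(np.abs(self(np.linspace(-1, 1, 101)))), 1e-300)
        if np.max(poles) > 1e-6 * scale:
            warnings.warn(
                f"slip profile {self.name!r} does not vanish at the poles "
                "(implies cortical sources/sinks there)",
                stacklevel=2,
            )

    def __call__(self, zeta):
        return self.amplitude * np.asarray(self.shape(np.asarray(zeta, dtype=float)))


@dataclass(frozen=True)
class ModeCoefficients:
    """Slip expansion coefficients ``B_1 .. B_nmax`` (um/s)."""

    B: np.ndarray

    @property
    def nmax(self) -> int:
        return len(self.B)

    def __getitem__(self, n: int) -> float:
        """B_n with the physical 1-based index."""
        return float(self.B[n - 1])


def compute_slip_coefficients(
    vs: SlipProfile | Callable,
    g: EmbryoGeometry,
    nmax: int = DEFAULT_NMAX,
    quad_nodes: int = 128,
) -> ModeCoefficients:
    """Project a slip profile onto the associated-Legendre basis.

        B_n = (2n + 1) / (2 n (n + 1) tau0) *
              int_{-1}^{1} v_s(zeta) sqrt(tau0^2 - zeta^2) P_n^1(zeta) dzeta

    Fixed-order Gauss-Legendre quadrature is used: the integrand is smooth on
    [-1, 1] because tau0 > 1 keeps the square root away from zero.
    """
    if nmax < 2:
        raise ValueError("nmax must be >= 2")
    vs_fun = vs if callable(vs) else vs.shape
    x, w = leggauss(quad_nodes)
    f = np.asarray(vs_fun(x), dtype=float) * np.sqrt(g.tau0**2 - x**2)
    B = np.empty(nmax)
    for n in range(1, nmax + 1):
        B[n - 1] = (
            (2 * n + 1) / (2 * n * (n + 1) * g.tau0) * np.sum(w * f * assoc_legendre_P1(n, x))
        )
    return ModeCoefficients(B=B)


def reconstruct_slip(B: ModeCoefficients, g: EmbryoGeometry, zeta) -> np.ndarray:
    """Evaluate the truncated slip expansion at ``zeta`` (um/s)."""
    zeta = np.asarray(zeta, dtype=float)
    s = np.zeros_like(zeta)
    for n in range(1, B.nmax + 1):
        s += B[n] * assoc_legendre_P1(n, zeta)
    return g.tau0 / np.sqrt(g.tau0**2 - zeta**2) * s


@dataclass(frozen=True)
class SeriesCoefficients:
    """Solved streamfunction series for one geometry and slip profile.

    ``coef[i, k]`` is the weight of ``G_k(tau)`` in ``g_n(tau)`` for
    ``n = orders[i]``; ``E`` and ``F`` are the named constants of the radial
    combinations.  ``g_n(tau0) = 0`` holds by construction for every order.
    """

    geometry: EmbryoGeometry
    nmax: int
    B: ModeCoefficients
    orders: np.ndarray  # retained n values (2 .. nmax + 1)
    coef: np.ndarray  # (len(orders), kmax + 1) weights of G_k(tau)
    E: dict = field(default_factory=dict)
    F: dict = field(default_factory=dict)

    @property
    def kmax(self) -> int:
        return self.coef.shape[1] - 1

    def g_and_dg(self, tau):
        """``g_n(tau)`` and ``g_n'(tau)`` for all retained orders.

        Returns arrays of shape ``(len(orders),) + tau.shape``.
        """
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        Gt = gegenbauer_table(self.kmax, tau)
        Pt, _ = legendre_table(self.kmax, tau)
        dGt = np.zeros_like(Gt)
        dGt[1:] = -Pt[:-1]  # dG_k/dx = -P_{k-1}
        gs = np.tensordot(self.coef, Gt, axes=(1, 0))
        dgs = np.tensordot(self.coef, dGt, axes=(1, 0))
        return gs, dgs

    def to_json(self) -> str:
        payload = {
            "geometry": {"bx_um": self.geometry.bx, "bz_um": self.geometry.bz,
                         "c_um": self.geometry.c, "tau0": self.geometry.tau0},
            "nmax": self.nmax,
            "B": list(map(float, self.B.B)),
            "E": {str(k): float(v) for k, v in sorted(self.E.items())},
            "F": {str(k): float(v) for k, v in sorted(self.F.items())},
        }
        return json.dumps(payload, indent=2)


def solve_series(B: ModeCoefficients, g: EmbryoGeometry) -> SeriesCoefficients:
    """Solve the two boundary-condition ladders for ``{E_n, F_n}``.

    Each slip mode ``B_{n-1}`` forces the radial function ``g_n``; the
    conditions ``g_n(tau0) = 0`` and ``g_n'(tau0) = tau0 c^2 n (n-1) B_{n-1}``
    determine ``(F_n, E_{n+2})`` once ``E_n`` is known from two orders below.
    The even (n = 2, 4, ...) and odd (n = 3, 5, ...) chains are independent.
    """
    nmax = B.nmax
    orders = np.arange(2, nmax + 2)
    kmax = nmax + 3
    coef = np.zeros((len(orders), kmax + 1))
    E: dict[int, float] = {}
    F: dict[int, float] = {}
    tau0 = g.tau0
    for start in (2, 3):
        e_prev = 0.0
        for n in range(start, nmax + 2, 2):
            rhs = tau0 * g.c**2 * n * (n - 1) * B[n - 1]
            A = np.array(
                [
                    [float(gegenbauer_G(n, tau0)), float(gegenbauer_G(n + 2, tau0))],
                    [float(gegenbauer_G_prime(n, tau0)), float(gegenbauer_G_prime(n + 2, tau0))],
                ]
            )
            b = np.array([0.0, rhs])
            if n >= 4:
                b -= e_prev * np.array(
                    [float(gegenbauer_G(n - 2, tau0)), float(gegenbauer_G_prime(n - 2, tau0))]
                )
            try:
                fn, e_next = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    f"singular 2x2 step system at order n={n}"
                ) from exc
            i = n - 2
            coef[i, n] += fn
            coef[i, n + 2] += e_next
            if n >= 4:
                coef[i, n - 2] += e_prev
            F[n] = float(fn)
            E[n + 2] = float(e_next)
            e_prev = e_next
    return SeriesCoefficients(geometry=g, nmax=nmax, B=B, orders=orders, coef=coef, E=E, F=F)


def solve_slip_flow(
    vs: SlipProfile | Callable,
    g: EmbryoGeometry,
    nmax: int = DEFAULT_NMAX,
) -> SeriesCoefficients:
    """Convenience: slip profile -> mode coefficients -> solved series."""
    return solve_series(compute_slip_coefficients(vs, g, nmax), g)


def _zeta_tables(coeffs: SeriesCoefficients, zeta):
    """Legendre/Gegenbauer tables over zeta needed by the series sums."""
    kmax = int(coeffs.orders[-1])
    P, dP = legendre_table(kmax, zeta)
    return P, dP


def streamfunction(coeffs: SeriesCoefficients, tau, zeta) -> np.ndarray:
    """Stokes streamfunction ``psi(tau, zeta)`` (um^3/s scale).

    Vanishes identically on the boundary ``tau = tau0`` and on the axis
    ``zeta = +/-1``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    zeta = np.atleast_1d(np.asarray(zeta, dtype=float))
    tau, zeta = np.broadcast_arrays(tau, zeta)
    gs, _ = coeffs.g_and_dg(tau)
    Gz = gegenbauer_table(int(coeffs.orders[-1]), zeta)
    psi = np.zeros(tau.shape)
    for i, n in enumerate(coeffs.orders):
        psi += gs[i] * Gz[n]
    return psi


def velocity_spheroidal(coeffs: SeriesCoefficients, tau, zeta):
    """Spheroidal velocity components ``(u_tau, u_zeta)`` (um/s).

    Requires ``tau > 1`` and ``|zeta| < 1`` (the spheroidal frame is
    degenerate elsewhere); use :func:`velocity_rz` for axis points.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    zeta = np.atleast_1d(np.asarray(zeta, dtype=float))
    tau, zeta = np.broadcast_arrays(tau, zeta)
    c = coeffs.geometry.c
    gs, dgs = coeffs.g_and_dg(tau)
    P, dP = _zeta_tables(coeffs, zeta)
    psi_zeta = np.zeros(tau.shape)
    S2 = np.zeros(tau.shape)  # sum g_n' P'_{n-1} / (n (n-1))
    for i, n in enumerate(coeffs.orders):
        psi_zeta -= gs[i] * P[n - 1]
        S2 += dgs[i] * dP[n - 1] / (n * (n - 1))
    u_tau = psi_zeta / (c**2 * np.sqrt((tau**2 - zeta**2) * (tau**2 - 1.0)))
    u_zeta = -np.sqrt(1.0 - zeta**2) * S2 / (c**2 * np.sqrt(tau**2 - zeta**2))
    return u_tau, u_zeta


def velocity_rz(coeffs: SeriesCoefficients, r, z):
    """Cylindrical velocity components ``(u_r, u_z)`` (um/s) at ``(r, z)``.

    Formulated to be regular on the axis: ``u_z`` uses
    ``(zeta psi_zeta - tau psi_tau) / (c^2 (tau^2 - zeta^2))`` and the
    ``1/sqrt(1-zeta^2)`` factors of the spheroidal frame are absorbed
    analytically via ``G_n(zeta) = (1-zeta^2) P'_{n-1}(zeta) / (n(n-1))``.
    On the axis ``u_r = 0`` by symmetry.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    r, z = np.broadcast_arrays(r, z)
    g = coeffs.geometry
    c = g.c
    tau, zeta = to_spheroidal(r, z, g, rtol=1e-6)
    gs, dgs = coeffs.g_and_dg(tau)
    P, dP = _zeta_tables(coeffs, zeta)
    psi_zeta = np.zeros(tau.shape)
    psi_tau = np.zeros(tau.shape)
    S2 = np.zeros(tau.shape)
    for i, n in enumerate(coeffs.orders):
        Pn1 = P[n - 1]
        psi_zeta -= gs[i] * Pn1
        psi_tau += dgs[i] * (1.0 - zeta**2) * dP[n - 1] / (n * (n - 1))
        S2 += dgs[i] * dP[n - 1] / (n * (n - 1))
    denom = c**2 * (tau**2 - zeta**2)
    u_z = (zeta * psi_zeta - tau * psi_tau) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        u_r = (
            np.sqrt((tau**2 - 1.0) * (1.0 - zeta**2))
            * (tau / (tau**2 - 1.0) * psi_zeta + zeta * S2)
            / denom
        )
    u_r = np.where(r < 1e-9, 0.0, u_r)
    return u_r, u_z


class StokesFlowField:
    """Unit-amplitude exact flow field, the advection backend of transport.

    Wraps a solved :class:`SeriesCoefficients`; exposes the meridional
    velocity ``velocity_rz`` and the full 3D Cartesian velocity
    ``velocity_xyz`` (the flow is axisymmetric, so the azimuth of each point
    is preserved under advection).
    """

    def __init__(self, coeffs: SeriesCoefficients):
        self.coeffs = coeffs
        self.geometry = coeffs.geometry

    def velocity_rz(self, r, z):
        return velocity_rz(self.coeffs, r, z)

    def velocity_xyz(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rr = np.hypot(pts[:, 0], pts[:, 1])
        u_r, u_z = self.velocity_rz(rr, pts[:, 2])
        with np.errstate(invalid="ignore", divide="ignore"):
            cosp = np.where(rr > 0, pts[:, 0] / rr, 0.0)
            sinp = np.where(rr > 0, pts[:, 1] / rr, 0.0)
        return np.column_stack([u_r * cosp, u_r * sinp, u_z])


def truncation_study(
    vs: SlipProfile | Callable,
    g: EmbryoGeometry,
    n_low: int,
    n_high: int,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    floor_frac: float = 0.01,
) -> float:
    """Max relative velocity difference between two truncation orders.

    Compares ``|u_low - u_high| / max|u_high|`` over an interior grid,
    excluding points where the flow magnitude is below ``floor_frac`` of its
    global maximum (where relative differences are meaningless).
    """
    if n_low > n_high:
        raise ValueError("need n_low <= n_high")
    lo = solve_slip_flow(vs, g, n_low)
    hi = solve_slip_flow(vs, g, n_high)
    if grid is None:
        # interior grid with a 5% boundary margin: truncation error
        # concentrates in the near-boundary pole caps where the flow itself
        # is nearly zero
        zg = np.linspace(-0.95 * g.bz, 0.95 * g.bz, 81)
        rg = np.linspace(0.0, 0.95 * g.bx, 41)
        R, Z = np.meshgrid(rg, zg)
        keep = g.contains_rz(R / 0.95, Z / 0.95)
        grid = (R[keep], Z[keep])
    r, z = grid
    ur_l, uz_l = velocity_rz(lo, r, z)
    ur_h, uz_h = velocity_rz(hi, r, z)
    mag_h = np.hypot(ur_h, uz_h)
    umax = mag_h.max()
    diff = np.hypot(ur_l - ur_h, uz_l - uz_h)
    keep = mag_h >= floor_frac * umax
    return float(np.max(diff[keep]) / umax)


def count_vortices(
    coeffs: SeriesCoefficients,
    g: EmbryoGeometry | None = None,
    grid_shape: tuple[int, int] = (60, 160),
    floor: float = 1e-8,
) -> int:
    """Number of meridional vortices of the flow.

    Counts connected sign regions of the streamfunction on the (r, z)
    half-plane cross-section: each closed recirculation cell is a region of
    single-signed psi.  A slip made of the single mode ``B_m`` produces
    exactly m vortices.
    """
    g = g or coeffs.geometry
    nr, nz = grid_shape
    rg = np.linspace(0.02 * g.bx, 0.95 * g.bx, nr)
    zg = np.linspace(-0.97 * g.bz, 0.97 * g.bz, nz)
    R, Z = np.meshgrid(rg, zg, indexing="ij")
    inside = g.contains_rz(R / 0.97, Z / 0.97)
    tau, zeta = to_spheroidal(np.where(inside, R, 0.0), np.where(inside, Z, 0.0), g)
    psi = streamfunction(coeffs, tau, zeta)
    return _count_sign_regions(np.where(inside, psi, 0.0), floor)


def _count_sign_regions(psi: np.ndarray, floor: float = 1e-8) -> int:
    """Connected single-signed regions of a sampled streamfunction."""
    pmax = np.max(np.abs(psi))
    if pmax <= floor:
        raise ValueError("flow magnitude below numerical floor; no vortices to count")
    count = 0
    for sgn in (1.0, -1.0):
        mask = sgn * psi > 1e-4 * pmax
        _, ncomp = ndimage.label(mask)
        count += ncomp
    return int(count)
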