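"""Prolate spheroidal geometry and the special functions of the flow series.

The cell is a prolate spheroid of semi-minor axis ``bx`` and semi-major axis
``bz`` (both in um), elongated along the z-axis.  Modified prolate spheroidal
coordinates ``(tau, zeta, phi)`` are used throughout:

    r = c * sqrt(tau^2 - 1) * sqrt(1 - zeta^2),    z = c * tau * zeta,

with semi-focal distance ``c = sqrt(bz^2 - bx^2)``.  Surfaces of constant
``tau`` are confocal spheroids; the cell boundary is ``tau = tau0 = bz / c``
and the interior is ``1 <= tau < tau0``.  The degenerate surface ``tau = 1``
is the focal segment ``|z| <= c`` on the axis.  On the boundary ``zeta`` is a
rescaled axial position, ``zeta = z / bz``.

All lengths are in um, velocities in um/s, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, lpmv

__all__ = [
    "EmbryoGeometry",
    "make_geometry",
    "to_cylindrical",
    "to_spheroidal",
    "metric_coefficients",
    "basis_vectors",
    "gegenbauer_G",
    "gegenbauer_G_prime",
    "assoc_legendre_P1",
    "legendre_table",
    "gegenbauer_table",
]


@dataclass(frozen=True)
class EmbryoGeometry:
    """Prolate spheroidal cell geometry.

    Attributes
    ----------
    bx : float
        Semi-minor axis (um).
    bz : float
        Semi-major axis (um).
    c : float
        Semi-focal distance ``sqrt(bz^2 - bx^2)`` (um).
    tau0 : float
        Dimensionless boundary coordinate ``bz / c`` (> 1).
    """

    bx: float
    bz: float
    c: float
    tau0: float

    def contains_rz(self, r, z, rtol: float = 0.0):
        """Boolean mask of meridional points inside (or on) the spheroid."""
        return (np.asarray(r) / self.bx) ** 2 + (np.asarray(z) / self.bz) ** 2 <= 1.0 + rtol

    def radius_at(self, z):
        """Cross-sectional radius R(z) = bx * sqrt(1 - (z/bz)^2)."""
        return self.bx * np.sqrt(np.clip(1.0 - (np.asarray(z) / self.bz) ** 2, 0.0, None))


def make_geometry(bx: float, bz: float) -> EmbryoGeometry:
    """Build an :class:`EmbryoGeometry` from its two semi-axes (um).

    Requires ``0 < bx < bz`` (a prolate spheroid elongated along z); oblate
    or degenerate shapes are rejected.
    """
    if not (0.0 < bx < bz):
        raise ValueError(
            f"need 0 < bx < bz for a prolate spheroid, got bx={bx}, bz={bz}"
        )
    c = float(np.sqrt(bz**2 - bx**2))
    return EmbryoGeometry(bx=float(bx), bz=float(bz), c=c, tau0=bz / c)


def to_cylindrical(tau, zeta, g: EmbryoGeometry):
    """Map spheroidal ``(tau, zeta)`` to cylindrical ``(r, z)`` in um."""
    tau = np.asarray(tau, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    r = g.c * np.sqrt(np.clip(tau**2 - 1.0, 0.0, None) * np.clip(1.0 - zeta**2, 0.0, None))
    z = g.c * tau * zeta
    return r, z


def to_spheroidal(r, z, g: EmbryoGeometry, rtol: float = 1e-9):
    """Map cylindrical ``(r, z)`` to spheroidal ``(tau, zeta)``.

    Uses the focal-distance identities ``d1 +/- d2 = 2 c tau, 2 c zeta`` with
    ``d1, d2`` the distances to the two foci, which are numerically stable
    everywhere including the axis and the focal segment.  Points outside the
    spheroid (``tau > tau0`` beyond ``rtol``) are rejected.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    d1 = np.hypot(r, z + g.c)
    d2 = np.hypot(r, z - g.c)
    tau = (d1 + d2) / (2.0 * g.c)
    zeta = (d1 - d2) / (2.0 * g.c)
    if np.any(tau > g.tau0 * (1.0 + rtol)):
        raise ValueError("point(s) outside the spheroid (tau > tau0)")
    tau = np.clip(tau, 1.0, g.tau0)
    zeta = np.clip(zeta, -1.0, 1.0)
    return tau, zeta


def metric_coefficients(tau, zeta, g: EmbryoGeometry):
    """Lame metric coefficients ``(h_tau, h_zeta, h_phi)`` in um.

    ``h_tau`` degenerates on the focal segment (tau = 1) and ``h_phi``
    vanishes on the axis (|zeta| = 1); evaluation there raises.
    """
    tau = np.asarray(tau, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(tau <= 1.0) or np.any(np.abs(zeta) >= 1.0):
        raise ValueError("metric coefficients degenerate at tau=1 or |zeta|=1")
    h_tau = g.c * np.sqrt((tau**2 - zeta**2) / (tau**2 - 1.0))
    h_zeta = g.c * np.sqrt((tau**2 - zeta**2) / (1.0 - zeta**2))
    h_phi = g.c * np.sqrt((tau**2 - 1.0) * (1.0 - zeta**2))
    return h_tau, h_zeta, h_phi


def basis_vectors(tau, zeta, g: EmbryoGeometry):
    """Unit basis vectors ``e_tau`` and ``e_zeta`` as (e_r, e_z) components.

    Returns ``((etau_r, etau_z), (ezeta_r, ezeta_z))``.  The frame is
    orthonormal; it degenerates on the axis and focal segment.
    """
    tau = np.asarray(tau, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(tau <= 1.0) or np.any(np.abs(zeta) >= 1.0):
        raise ValueError("basis vectors degenerate at tau=1 or |zeta|=1")
    den = np.sqrt(tau**2 - zeta**2)
    etau_r = tau * np.sqrt(1.0 - zeta**2) / den
    etau_z = zeta * np.sqrt(tau**2 - 1.0) / den
    ezeta_r = -zeta * np.sqrt(tau**2 - 1.0) / den
    ezeta_z = tau * np.sqrt(1.0 - zeta**2) / den
    return (etau_r, etau_z), (ezeta_r, ezeta_z)


def gegenbauer_G(n: int, x):
    """Gegenbauer function of the first kind, order n, degree -1/2.

    ``G_0 = 1``, ``G_1 = -x`` and, for n >= 2,

        G_n(x) = (P_{n-2}(x) - P_n(x)) / (2n - 1),

    with ``P_k`` the Legendre polynomials.  The Legendre-difference form is a
    polynomial, so it extends analytically to arguments outside [-1, 1]
    (needed on the tau side of the series solution).  ``G_n(+/-1) = 0`` for
    n >= 2.
    """
    x = np.asarray(x, dtype=float)
    if n == 0:
        return np.ones_like(x)
    if n == 1:
        return -x
    return (eval_legendre(n - 2, x) - eval_legendre(n, x)) / (2 * n - 1)


def gegenbauer_G_prime(n: int, x):
    """Analytic derivative dG_n/dx = -P_{n-1}(x) for n >= 1 (0 for n = 0)."""
    x = np.asarray(x, dtype=float)
    if n == 0:
        return np.zeros_like(x)
    return -eval_legendre(n - 1, x)


def assoc_legendre_P1(n: int, x):
    """Associated Legendre function P_n^1(x) on [-1, 1].

    The sign convention (including the Condon-Shortley phase, as in
    :func:`scipy.special.lpmv`) is the one for which

        sqrt(1 - x^2) * P_l^1(x) = -l (l + 1) * G_{l+1}(x)

    holds identically; this identity ties the boundary-flow expansion to the
    streamfunction basis and is enforced by tests.
    """
    if n < 1:
        raise ValueError("assoc_legendre_P1 requires n >= 1")
    return lpmv(1, n, np.asarray(x, dtype=float))


def legendre_table(kmax: int, x):
    """Legendre polynomials and derivatives ``P_k(x), P_k'(x)``, k = 0..kmax.

    Three-term recurrence, vectorized over ``x``; returns two arrays of shape
    ``(kmax + 1,) + x.shape``.  Valid for any real argument.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    P = np.empty((kmax + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0] = 1.0
    dP[0] = 0.0
    if kmax >= 1:
        P[1] = x
        dP[1] = 1.0
    for k in range(1, kmax):
        P[k + 1] = ((2 * k + 1) * x * P[k] - k * P[k - 1]) / (k + 1)
        dP[k + 1] = dP[k - 1] + (2 * k + 1) * P[k]
    return P, dP


def gegenbauer_table(nmax: int, x):
    """``G_n(x)`` for n = 0..nmax as an array of shape ``(nmax+1,) + x.shape``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    P, _ = legendre_table(max(nmax, 1), x)
    G = np.empty((nmax + 1,) + x.shape)
    G[0] = 1.0
    if nmax >= 1:
        G[1] = -x
    for n in range(2, nmax + 1):
        G[n] = (P[n - 2] - P[n]) / (2 * n - 1)
    return G
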