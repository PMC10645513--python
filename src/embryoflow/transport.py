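"""Nuclear transport by cytoplasmic flow: advection, spreading and optimality.

Model nuclei are passive tracers advected by the cortically driven flow.  In
the Stokes regime the flow depends on time only through the boundary
amplitude ``V(t)``, so trajectories depend on ``V`` only through the rescaled
time

    chi := int_0^t V(t') dt'        (units: um),

roughly the distance travelled by cortical material points.  All advection is
therefore done in chi with the unit-amplitude flow field.

Axial spreading is measured by the variance of a kernel density estimate of
the tracers' axial positions,

    rho(z) = (1 / (N R sqrt(2 pi))) sum_i exp(-(z - z_i)^2 / (2 R^2)),
    Phi    = int_{-bz}^{bz} [rho(z) - rho_bar]^2 dz,

with the kernel bandwidth R set by the nuclear diameter (7 um) or the
nuclear separation distance (28 um), and also by a discrete strip-count
variance.  Ensembles over random initial clouds yield the mean homogeneity
curve <Phi(chi)>/<Phi(0)> and its optimal chi (argmin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths
from scipy.special import erf

from .geometry import EmbryoGeometry, to_cylindrical, to_spheroidal

__all__ = [
    "drosophila_slip",
    "stagnation_zeta",
    "ParticleCloud",
    "sample_initial_cloud",
    "advect",
    "density",
    "variance_phi",
    "discrete_variance",
    "TransportConfig",
    "HomogeneityCurve",
    "EnsembleTrajectories",
    "advect_ensemble",
    "ensemble_homogeneity",
    "GaussianSum",
    "chi_from_amplitude",
    "fit_amplitude_gaussians",
    "division_spread",
]

CLOUD_RADIUS_UM = 60.0  # initial nuclear cloud radius


def drosophila_slip(zeta):
    """Shifted-sine cortical flow shape of the early fly embryo (unit amplitude).

    ``v_s(zeta) = -sin(pi zeta + arcsin(1/3)) - 1/3``: cortical flows
    converge towards an off-centre point in the anterior half and vanish at
    both poles.  The single interior zero sits at
    ``zeta* = -2 arcsin(1/3) / pi ~ -0.2163``.
    """
    zeta = np.asarray(zeta, dtype=float)
    return -np.sin(np.pi * zeta + np.arcsin(1.0 / 3.0)) - 1.0 / 3.0


def stagnation_zeta() -> float:
    """Interior zero of the embryo slip shape, ``-2 arcsin(1/3) / pi``."""
    return -2.0 * np.arcsin(1.0 / 3.0) / np.pi


@dataclass
class ParticleCloud:
    """Positions of N model nuclei in 3D Cartesian um, with seed provenance."""

    positions: np.ndarray  # (N, 3)
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]


def sample_initial_cloud(
    N: int,
    seed: int | None,
    g: EmbryoGeometry,
    radius: float = CLOUD_RADIUS_UM,
    center: np.ndarray | None = None,
) -> ParticleCloud:
    """Uniform ball of N tracers around the axial stagnation point.

    The default centre is ``(0, 0, bz * zeta*)`` with ``zeta*`` the interior
    zero of the embryo slip shape, mimicking the nuclear cloud at the start
    of the spreading cell cycles.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if center is None:
        center = np.array([0.0, 0.0, g.bz * stagnation_zeta()])
    rng = np.random.default_rng(seed)
    pts = np.empty((N, 3))
    have = 0
    while have < N:
        cand = rng.uniform(-radius, radius, size=(max(2 * (N - have), 16), 3))
        good = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
        take = min(N - have, len(good))
        pts[have : have + take] = good[:take]
        have += take
    return ParticleCloud(positions=pts + center, seed=seed)


def sample_spheroidal_cloud(
    N: int,
    seed: int | None,
    semi_minor: float,
    semi_major: float,
    center: np.ndarray | None = None,
) -> ParticleCloud:
    """Uniform cloud inside a spheroid of given semi-axes (long axis along z).

    Used for the cell-division toy model, whose initial state is a packed
    spheroidal cloud of nuclei around the cell centre.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(N, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    rad = rng.uniform(0.0, 1.0, N) ** (1.0 / 3.0)
    pts = u * rad[:, None] * np.array([semi_minor, semi_minor, semi_major])
    if center is not None:
        pts = pts + center
    return ParticleCloud(positions=pts, seed=seed)


def _project_inside(pts: np.ndarray, g: EmbryoGeometry, margin: float = 1e-9) -> int:
    """Project stray particles just inside the boundary (in place).

    The exact flow satisfies no-penetration, so only integration round-off
    can push a particle out; projections move points radially (in tau) to
    ``tau0 * (1 - margin)``.  Returns the number of projected particles.
    """
    r = np.hypot(pts[:, 0], pts[:, 1])
    d1 = np.hypot(r, pts[:, 2] + g.c)
    d2 = np.hypot(r, pts[:, 2] - g.c)
    tau = (d1 + d2) / (2.0 * g.c)
    zeta = np.clip((d1 - d2) / (2.0 * g.c), -1.0, 1.0)
    out = tau > g.tau0 * (1.0 - margin)
    if not np.any(out):
        return 0
    tau_new = np.full(np.count_nonzero(out), g.tau0 * (1.0 - margin))
    r_new, z_new = to_cylindrical(tau_new, zeta[out], g)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r[out] > 0, r_new / r[out], 0.0)
    pts[out, 0] *= scale
    pts[out, 1] *= scale
    pts[out, 2] = z_new
    return int(np.count_nonzero(out))


def advect(
    cloud: ParticleCloud,
    flow,
    chi_targets: Sequence[float],
    dchi: float = 0.5,
    g: EmbryoGeometry | None = None,
) -> list[ParticleCloud]:
    """Advect a tracer cloud through the unit-amplitude flow.

    Classic RK4 in the rescaled time chi with fixed step ``dchi`` (um);
    snapshot values in ``chi_targets`` (increasing, >= 0) are hit exactly by
    shortening the final step.  Particles are kept inside the spheroid by a
    tiny radial projection after each step.
    """
    chi_targets = np.asarray(chi_targets, dtype=float)
    if np.any(np.diff(chi_targets) < 0) or chi_targets[0] < 0:
        raise ValueError("chi_targets must be non-decreasing and >= 0")
    g = g or flow.geometry
    x = cloud.positions.copy()
    out = []
    chi = 0.0
    for target in chi_targets:
        while chi < target - 1e-12:
            h = min(dchi, target - chi)
            k1 = flow.velocity_xyz(x)
            k2 = flow.velocity_xyz(x + 0.5 * h * k1)
            k3 = flow.velocity_xyz(x + 0.5 * h * k2)
            k4 = flow.velocity_xyz(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            _project_inside(x, g)
            chi += h
        out.append(ParticleCloud(positions=x.copy(), seed=cloud.seed))
    return out


def advect_time_domain(
    cloud: ParticleCloud,
    flow,
    amplitude: Callable[[float], float],
    t_end: float,
    dt: float = 1.0,
    g: EmbryoGeometry | None = None,
) -> ParticleCloud:
    """Advect in physical time with amplitude V(t); equivalent to chi advection.

    Provided for the reparameterization check ``dx/dt = V(t) u_hat(x)``; the
    final state must agree with chi-domain advection at chi = int_0^t V dt.
    """
    g = g or flow.geometry
    x = cloud.positions.copy()
    t = 0.0
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)

        def vel(ti, xi):
            return amplitude(ti) * flow.velocity_xyz(xi)

        k1 = vel(t, x)
        k2 = vel(t + 0.5 * h, x + 0.5 * h * k1)
        k3 = vel(t + 0.5 * h, x + 0.5 * h * k2)
        k4 = vel(t + h, x + h * k3)
        x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        _project_inside(x, g)
        t += h
    return ParticleCloud(positions=x, seed=cloud.seed)


def density(z_positions, kernel_bandwidth: float, z_grid) -> np.ndarray:
    """Gaussian-kernel axial density estimate, normalized to unit mass.

    ``rho(z) = (1/N) sum_i Normal(z; z_i, R^2)``; integrates to 1 over the
    real line (up to kernel tails outside the grid window).
    """
    if kernel_bandwidth <= 0:
        raise ValueError("kernel_bandwidth must be positive")
    z_positions = np.asarray(z_positions, dtype=float).ravel()
    z_grid = np.asarray(z_grid, dtype=float)
    d = z_grid[:, None] - z_positions[None, :]
    R = kernel_bandwidth
    return np.exp(-(d**2) / (2.0 * R**2)).mean(axis=1) / (R * np.sqrt(2.0 * np.pi))


def variance_phi(rho: np.ndarray, z_grid: np.ndarray) -> float:
    """Axial homogeneity measure ``Phi = int [rho - rho_bar]^2 dz`` (1/um).

    ``rho_bar`` is the mean of rho over the grid interval; trapezoidal
    quadrature.  Zero iff rho is constant on the interval.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    L = z_grid[-1] - z_grid[0]
    rho_bar = np.trapezoid(rho, z_grid) / L
    return float(np.trapezoid((rho - rho_bar) ** 2, z_grid))


def discrete_variance(z_positions, n_strips: int, g: EmbryoGeometry) -> float:
    """Population variance of per-strip particle counts.

    The embryo is cut into ``n_strips`` strips of equal width along z; the
    returned value is ``var(n_1, ..., n_strips)``.
    """
    if n_strips < 2:
        raise ValueError("n_strips must be >= 2")
    z = np.asarray(z_positions, dtype=float).ravel()
    edges = np.linspace(-g.bz, g.bz, n_strips + 1)
    counts, _ = np.histogram(z, bins=edges)
    return float(np.var(counts))


def _refine_argmin(xs: np.ndarray, ys: np.ndarray) -> float:
    """Quadratic interpolation of the argmin through the discrete minimum."""
    i = int(np.argmin(ys))
    if i == 0 or i == len(xs) - 1:
        return float(xs[i])
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(xs[i])
    return float(xs[i] + 0.5 * (y0 - y2) / denom * (xs[i + 1] - xs[i]))


@dataclass
class TransportConfig:
    """Configuration of an ensemble transport run."""

    geometry: EmbryoGeometry
    flow: object  # unit-amplitude flow field (exact or lubrication backend)
    n_particles: int = 40
    kernel_bandwidth: float = 7.0
    n_seeds: int = 100
    base_seed: int = 0
    chi_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 401.0, 2.0))
    dchi: float = 0.5
    z_grid_step: float = 1.0
    measure: str = "kernel"  # "kernel" | "strips"
    n_strips: int = 100


@dataclass
class HomogeneityCurve:
    """Ensemble homogeneity curve and its optimum.

    ``phi_mean`` is ``<Phi(chi)> / <Phi(0)>``; ``phi_min``/``phi_max`` are
    the normalized envelope over seeds; ``chi_star`` the refined argmin.
    """

    chi_grid: np.ndarray
    phi_mean: np.ndarray
    phi_min: np.ndarray
    phi_max: np.ndarray
    chi_star: float
    n_seeds: int
    kernel_bandwidth: float | None = None
    n_strips: int | None = None
    base_seed: int | None = None

    def value_at(self, chi: float) -> float:
        """Normalized mean variance at an arbitrary chi (linear interpolation)."""
        return float(np.interp(chi, self.chi_grid, self.phi_mean))

    def excess_at(self, chi: float) -> float:
        """How far above the curve minimum the value at ``chi`` sits."""
        return self.value_at(chi) - float(np.min(self.phi_mean))


class EnsembleTrajectories:
    """Axial tracer trajectories for a seeded ensemble, reusable across measures.

    Stores ``z`` of shape (n_chi, n_seeds, N) so that homogeneity curves for
    several kernel bandwidths or strip counts can be computed from a single
    advection pass.
    """

    def __init__(self, chi_grid, z, g: EmbryoGeometry, base_seed: int):
        self.chi_grid = np.asarray(chi_grid, dtype=float)
        self.z = z
        self.geometry = g
        self.base_seed = base_seed

    @property
    def n_seeds(self) -> int:
        return self.z.shape[1]

    def kernel_curve(self, kernel_bandwidth: float, z_grid_step: float = 1.0) -> HomogeneityCurve:
        g = self.geometry
        zg = np.arange(-g.bz, g.bz + 0.5 * z_grid_step, z_grid_step)
        nchi, nseeds, N = self.z.shape
        R = kernel_bandwidth
        norm = 1.0 / (N * R * np.sqrt(2.0 * np.pi))
        phi = np.empty((nchi, nseeds))
        for i in range(nchi):  # chunked over chi to bound memory
            d = zg[None, :, None] - self.z[i][:, None, :]
            rho = norm * np.exp(-(d**2) / (2.0 * R**2)).sum(axis=2)
            rho_bar = np.trapezoid(rho, zg, axis=1) / (2.0 * g.bz)
            phi[i] = np.trapezoid((rho - rho_bar[:, None]) ** 2, zg, axis=1)
        return self._curve(phi, kernel_bandwidth=kernel_bandwidth)

    def strip_curve(self, n_strips: int) -> HomogeneityCurve:
        g = self.geometry
        edges = np.linspace(-g.bz, g.bz, n_strips + 1)
        nchi, nseeds, _ = self.z.shape
        phi = np.empty((nchi, nseeds))
        for i in range(nchi):
            for s in range(nseeds):
                counts, _ = np.histogram(self.z[i, s], bins=edges)
                phi[i, s] = np.var(counts)
        return self._curve(phi, n_strips=n_strips)

    def _curve(self, phi: np.ndarray, **meta) -> HomogeneityCurve:
        mean0 = phi[0].mean()
        mean = phi.mean(axis=1) / mean0
        lo = phi.min(axis=1) / mean0
        hi = phi.max(axis=1) / mean0
        return HomogeneityCurve(
            chi_grid=self.chi_grid,
            phi_mean=mean,
            phi_min=lo,
            phi_max=hi,
            chi_star=_refine_argmin(self.chi_grid, mean),
            n_seeds=self.n_seeds,
            base_seed=self.base_seed,
            **meta,
        )


def advect_ensemble(
    flow,
    g: EmbryoGeometry,
    n_particles: int,
    n_seeds: int,
    base_seed: int,
    chi_grid,
    dchi: float = 0.5,
) -> EnsembleTrajectories:
    """Advect ``n_seeds`` independent clouds (seeds ``base_seed + k``) at once.

    All clouds are stacked into a single particle array so the series
    evaluation is vectorized across the whole ensemble.
    """
    chi_grid = np.asarray(chi_grid, dtype=float)
    clouds = [
        sample_initial_cloud(n_particles, base_seed + k, g) for k in range(n_seeds)
    ]
    stacked = ParticleCloud(np.concatenate([c.positions for c in clouds]), seed=base_seed)
    snaps = advect(stacked, flow, chi_grid, dchi=dchi, g=g)
    z = np.stack([s.positions[:, 2].reshape(n_seeds, n_particles) for s in snaps])
    return EnsembleTrajectories(chi_grid, z, g, base_seed)


def ensemble_homogeneity(config: TransportConfig) -> HomogeneityCurve:
    """Run a seeded ensemble and return its homogeneity curve.

    With ``measure="kernel"`` uses the Gaussian-kernel variance at
    ``config.kernel_bandwidth``; with ``measure="strips"`` the discrete
    strip-count variance at ``config.n_strips``.
    """
    if config.n_seeds < 2:
        raise ValueError("need at least 2 seeds for an ensemble")
    traj = advect_ensemble(
        config.flow,
        config.geometry,
        config.n_particles,
        config.n_seeds,
        config.base_seed,
        config.chi_grid,
        dchi=config.dchi,
    )
    if config.measure == "kernel":
        return traj.kernel_curve(config.kernel_bandwidth, config.z_grid_step)
    if config.measure == "strips":
        return traj.strip_curve(config.n_strips)
    raise ValueError(f"unknown measure {config.measure!r}")


@dataclass(frozen=True)
class GaussianSum:
    """Cortical amplitude model ``V(t) = sum_i a_i exp(-(t-b_i)^2 / 2 c_i^2)``.

    ``a`` in um/s, ``b`` and ``c`` in s.  The all-time integral is
    ``sum_i a_i c_i sqrt(2 pi)`` — the total chi the amplitude realizes.
    """

    a: tuple
    b: tuple
    c: tuple

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for ai, bi, ci in zip(self.a, self.b, self.c):
            out = out + ai * np.exp(-((t - bi) ** 2) / (2.0 * ci**2))
        return out

    def chi_total(self) -> float:
        return float(np.sqrt(2.0 * np.pi) * sum(ai * ci for ai, ci in zip(self.a, self.c)))

    def chi_at(self, t: float) -> float:
        """``int_0^t V`` via the Gaussian error function."""
        total = 0.0
        for ai, bi, ci in zip(self.a, self.b, self.c):
            s = ci * np.sqrt(2.0)
            total += ai * ci * np.sqrt(np.pi / 2.0) * (erf((t - bi) / s) - erf((0.0 - bi) / s))
        return float(total)


def chi_from_amplitude(V, t: float | None = None, t_samples=None) -> float:
    """Rescaled time ``chi = int_0^t V(t') dt'`` (um).

    ``V`` may be a :class:`GaussianSum`, a callable (integrated by adaptive
    quadrature up to ``t``) or tabulated samples (``t_samples`` given;
    trapezoidal rule, integrated to the end of the table or to ``t``).
    """
    if isinstance(V, GaussianSum):
        return V.chi_at(t) if t is not None else V.chi_total()
    if t_samples is not None:
        ts = np.asarray(t_samples, dtype=float)
        vs = np.asarray(V, dtype=float)
        if t is not None:
            keep = ts <= t
            ts, vs = ts[keep], vs[keep]
        return float(np.trapezoid(vs, ts))
    if t is None:
        raise ValueError("an end time t is required for a callable amplitude")
    val, _ = quad(V, 0.0, t, limit=200)
    return float(val)


def fit_amplitude_gaussians(
    t_samples,
    v_samples,
    n_peaks: int = 3,
    peak_calibration: float | None = None,
):
    """Least-squares fit of a Gaussian sum to an amplitude time series.

    Peaks are initialized from local maxima above half the global maximum.
    If ``peak_calibration`` is given, the samples are first rescaled so the
    largest fitted peak amplitude equals it (used to convert RMS bulk-flow
    time series into cortical amplitudes, e.g. 0.3 um/s at the strongest
    contraction peak).

    Returns ``(GaussianSum, stderr)`` where ``stderr`` is a dict with
    1-sigma parameter errors and the propagated uncertainty of total chi.
    """
    t = np.asarray(t_samples, dtype=float)
    v = np.asarray(v_samples, dtype=float)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    span = t[-1] - t[0]
    idx, props = find_peaks(v, prominence=0.05 * v.max())
    if len(idx) >= n_peaks:  # keep the n_peaks most prominent
        idx = idx[np.argsort(props["prominences"])[::-1][:n_peaks]]
    else:  # supplement with evenly spaced seeds
        extra = np.linspace(0, len(t) - 1, n_peaks - len(idx) + 2)[1:-1].astype(int)
        idx = np.concatenate([idx, extra])
    widths = peak_widths(v, np.sort(idx), rel_height=0.5)[0] * np.median(np.diff(t))
    widths = np.clip(widths / 2.355, 0.02 * span, 0.5 * span)  # FWHM -> sigma
    p0 = []
    for i, w in zip(np.sort(idx), widths):
        p0 += [max(v[i], 0.05 * v.max()), t[i], w]

    def model(ti, *params):
        out = np.zeros_like(ti)
        for j in range(n_peaks):
            a, b, c = params[3 * j : 3 * j + 3]
            out = out + a * np.exp(-((ti - b) ** 2) / (2.0 * c**2))
        return out

    lo = [0.0, t[0] - span, 1e-3 * span] * n_peaks
    hi = [4.0 * v.max(), t[-1] + span, span] * n_peaks
    popt, pcov = curve_fit(model, t, v, p0=p0, bounds=(lo, hi), maxfev=20000)
    popt = np.asarray(popt)
    if peak_calibration is not None:
        scale = peak_calibration / np.max(popt[0::3])
        popt[0::3] *= scale
        pcov = pcov.copy()
        pcov[0::3, :] *= scale
        pcov[:, 0::3] *= scale
    gs = GaussianSum(a=tuple(popt[0::3]), b=tuple(popt[1::3]), c=tuple(popt[2::3]))
    # chi_total = sqrt(2 pi) sum a_i c_i; delta-method error from the covariance
    grad = np.zeros_like(popt)
    grad[0::3] = np.sqrt(2.0 * np.pi) * popt[2::3]
    grad[2::3] = np.sqrt(2.0 * np.pi) * popt[0::3]
    chi_var = float(grad @ pcov @ grad)
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    stderr = {
        "a": perr[0::3],
        "b": perr[1::3],
        "c": perr[2::3],
        "chi_total": float(np.sqrt(max(chi_var, 0.0))),
    }
    return gs, stderr


def division_spread(
    cloud: ParticleCloud,
    g: EmbryoGeometry,
    repulsion_range: float = 28.0,
    seed: int | None = None,
    step: float = 2.0,
    tol: float = 0.01,
    max_iter: int = 2000,
) -> ParticleCloud:
    """One round of nuclear division with short-range repulsive relaxation.

    Each nucleus is duplicated (daughters offset by a small random
    displacement) and the doubled cloud relaxes under pairwise linear-spring
    repulsion ``f(d) = max(0, 1 - d / range)`` with overdamped Euler steps
    until the largest displacement per step falls below ``tol`` um.
    Particles are confined to the spheroid by radial projection.  The force
    law is a modelling choice — only the sign of the induced change in the
    spreading measure is meaningful, not its magnitude.
    """
    rng = np.random.default_rng(seed)
    offs = rng.normal(scale=0.5, size=cloud.positions.shape)
    pts = np.concatenate([cloud.positions - offs, cloud.positions + offs])
    _project_inside(pts, g, margin=1e-6)
    n = len(pts)
    for _ in range(max_iter):
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        mag = np.clip(1.0 - dist / repulsion_range, 0.0, None)
        force = np.einsum("ij,ijk->ik", mag / dist, diff)
        disp = step * force
        max_disp = np.max(np.hypot(np.hypot(disp[:, 0], disp[:, 1]), disp[:, 2]))
        pts += disp
        _project_inside(pts, g, margin=1e-6)
        if max_disp < tol:
            break
    else:
        raise RuntimeError(
            f"division relaxation did not converge: last step moved {max_disp:.3g} um"
        )
    return ParticleCloud(positions=pts, seed=seed)
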