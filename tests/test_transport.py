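"""Tracer advection, spreading measures, amplitude handling, division model."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.spatial import ConvexHull

import embryoflow as ef
from embryoflow.transport import advect_time_domain, sample_spheroidal_cloud


class TestSlipShape:
    def test_vanishes_at_poles(self):
        assert float(ef.drosophila_slip(1.0)) == pytest.approx(0.0, abs=1e-15)
        assert float(ef.drosophila_slip(-1.0)) == pytest.approx(0.0, abs=1e-15)

    def test_single_interior_zero_at_stagnation_point(self):
        zstar = ef.stagnation_zeta()
        assert zstar == pytest.approx(-0.2163, abs=5e-5)
        assert float(ef.drosophila_slip(zstar)) == pytest.approx(0.0, abs=1e-14)
        zg = np.linspace(-0.999, 0.999, 4001)
        signs = np.sign(ef.drosophila_slip(zg))
        assert np.count_nonzero(np.diff(signs)) == 1  # one interior crossing


class TestInitialCloud:
    def test_within_ball_and_reproducible(self, embryo):
        c1 = ef.sample_initial_cloud(500, 7, embryo)
        c2 = ef.sample_initial_cloud(500, 7, embryo)
        center = np.array([0.0, 0.0, embryo.bz * ef.stagnation_zeta()])
        d = np.linalg.norm(c1.positions - center, axis=1)
        assert np.max(d) <= 60.0
        assert np.array_equal(c1.positions, c2.positions)
        c3 = ef.sample_initial_cloud(500, 8, embryo)
        assert not np.array_equal(c1.positions, c3.positions)

    def test_uniform_ball_moments(self, embryo):
        cloud = ef.sample_initial_cloud(100_000, 0, embryo)
        center = np.array([0.0, 0.0, embryo.bz * ef.stagnation_zeta()])
        rel = cloud.positions - center
        assert np.max(np.abs(rel.mean(axis=0))) < 1.0
        msr = np.mean(np.sum(rel**2, axis=1))
        assert msr == pytest.approx(0.6 * 60.0**2, rel=0.02)


class TestAdvection:
    def test_chi_zero_is_identity(self, embryo, drosophila_flow):
        cloud = ef.sample_initial_cloud(20, 1, embryo)
        snap = ef.advect(cloud, drosophila_flow, [0.0])[0]
        assert np.array_equal(snap.positions, cloud.positions)

    def test_axis_stagnation_point_is_fixed(self, embryo, drosophila_flow):
        # locate the axis zero of u_z, then advect a particle placed there
        zg = np.linspace(-80.0, -40.0, 4001)
        _, uz = drosophila_flow.velocity_rz(np.zeros_like(zg), zg)
        i = int(np.argmin(np.abs(uz)))
        z0 = zg[i] - uz[i] * (zg[1] - zg[0]) / (uz[i + 1] - uz[i])
        cloud = ef.ParticleCloud(np.array([[0.0, 0.0, z0]]), seed=None)
        snap = ef.advect(cloud, drosophila_flow, [200.0])[0]
        assert np.linalg.norm(snap.positions[0] - cloud.positions[0]) < 0.5

    def test_particles_stay_inside_and_keep_azimuth(self, embryo, drosophila_flow):
        cloud = ef.sample_initial_cloud(100, 2, embryo)
        snaps = ef.advect(cloud, drosophila_flow, [100.0, 300.0])
        phi0 = np.arctan2(cloud.positions[:, 1], cloud.positions[:, 0])
        for snap in snaps:
            p = snap.positions
            assert np.all((p[:, 0] ** 2 + p[:, 1] ** 2) / embryo.bx**2
                          + p[:, 2] ** 2 / embryo.bz**2 <= 1.0 + 1e-9)
            phi = np.arctan2(p[:, 1], p[:, 0])
            dphi = np.angle(np.exp(1j * (phi - phi0)))
            assert np.max(np.abs(dphi)) < 1e-9

    def test_time_domain_equals_chi_domain(self, embryo, drosophila_flow):
        # the state depends on V(t) only through chi = int V dt
        gs = ef.GaussianSum(a=(0.25, 0.1), b=(120.0, 320.0), c=(40.0, 25.0))
        cloud = ef.sample_initial_cloud(25, 4, embryo)
        t_end = 450.0
        chi_end = gs.chi_at(t_end)
        via_chi = ef.advect(cloud, drosophila_flow, [chi_end])[0]
        via_time = advect_time_domain(cloud, drosophila_flow, gs, t_end, dt=0.5)
        assert np.max(np.abs(via_chi.positions - via_time.positions)) < 1e-6

    def test_two_amplitudes_same_chi_same_state(self, embryo, drosophila_flow):
        cloud = ef.sample_initial_cloud(15, 9, embryo)
        a = advect_time_domain(
            cloud, drosophila_flow, lambda t: 0.3, 200.0, dt=0.5
        )
        b = advect_time_domain(
            cloud, drosophila_flow, lambda t: 0.1, 600.0, dt=1.5
        )
        assert np.max(np.abs(a.positions - b.positions)) < 1e-6

    def test_material_volume_conserved(self, embryo, drosophila_flow):
        # incompressibility: enclosed volume of an advected triangulated
        # material surface stays constant (signed-volume formula, valid for
        # the non-convex shapes the shell develops at large chi)
        rng = np.random.default_rng(3)
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pts0 = u * 55.0
        faces = ConvexHull(pts0).simplices.copy()
        a, b, c = pts0[faces[:, 0]], pts0[faces[:, 1]], pts0[faces[:, 2]]
        flip = np.einsum("ij,ij->i", a, np.cross(b, c)) < 0
        faces[flip] = faces[flip][:, ::-1]

        def vol(pts):
            a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
            return np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0

        center = np.array([0.0, 0.0, embryo.bz * ef.stagnation_zeta()])
        cloud = ef.ParticleCloud(pts0 + center, seed=3)
        snap = ef.advect(cloud, drosophila_flow, [300.0])[0]
        assert vol(snap.positions) == pytest.approx(vol(pts0), rel=0.01)


class TestDensityAndVariance:
    def test_single_particle_peak(self):
        zg = np.linspace(-50.0, 50.0, 101)
        rho = ef.density(np.array([10.0]), 7.0, zg)
        assert rho.max() == pytest.approx(1.0 / (7.0 * np.sqrt(2 * np.pi)), rel=1e-12)
        assert zg[np.argmax(rho)] == pytest.approx(10.0, abs=0.5)

    def test_coincident_particles_match_single(self):
        zg = np.linspace(-50.0, 50.0, 101)
        one = ef.density(np.array([5.0]), 7.0, zg)
        many = ef.density(np.full(40, 5.0), 7.0, zg)
        assert np.allclose(one, many, atol=1e-15)

    def test_two_particle_hand_evaluation(self):
        zg = np.linspace(-80.0, 80.0, 20)
        R = 7.0
        rho = ef.density(np.array([-50.0, 50.0]), R, zg)
        expect = (
            np.exp(-((zg + 50.0) ** 2) / (2 * R**2))
            + np.exp(-((zg - 50.0) ** 2) / (2 * R**2))
        ) / (2 * R * np.sqrt(2 * np.pi))
        assert np.allclose(rho, expect, rtol=1e-12)

    def test_density_integrates_to_one(self, embryo):
        zg = np.arange(-embryo.bz, embryo.bz + 0.5, 1.0)
        rho = ef.density(np.array([-40.0, 0.0, 55.0]), 7.0, zg)
        assert np.trapezoid(rho, zg) == pytest.approx(1.0, abs=1e-6)

    def test_variance_phi_examples(self, embryo):
        zg = np.arange(-embryo.bz, embryo.bz + 0.5, 1.0)
        assert ef.variance_phi(np.full_like(zg, 0.7), zg) == pytest.approx(0.0, abs=1e-15)
        rho_bar = 1.0 / (2 * embryo.bz)
        rho = rho_bar * (1.0 + np.cos(np.pi * zg / embryo.bz))
        # int cos^2(pi z / bz) dz over [-bz, bz] = bz
        assert ef.variance_phi(rho, zg) == pytest.approx(rho_bar**2 * embryo.bz, rel=1e-4)
        shifted = rho + 0.123
        assert ef.variance_phi(shifted, zg) == pytest.approx(
            ef.variance_phi(rho, zg), rel=1e-9
        )

    def test_discrete_variance(self, embryo):
        # all N particles in one strip of 10: counts are (N, 0, ..., 0)
        z = np.full(40, 5.0)
        counts = np.zeros(10)
        counts[0] = 40
        assert ef.discrete_variance(z, 10, embryo) == pytest.approx(np.var(counts))
        # equal counts in all strips -> zero variance
        edges = np.linspace(-embryo.bz, embryo.bz, 11)
        centers = 0.5 * (edges[:-1] + edges[1:])
        z = np.repeat(centers, 4)
        assert ef.discrete_variance(z, 10, embryo) == 0.0


@pytest.fixture(scope="module")
def small_curve(embryo, drosophila_flow):
    cfg = ef.TransportConfig(
        geometry=embryo,
        flow=drosophila_flow,
        n_particles=20,
        n_seeds=8,
        base_seed=11,
        chi_grid=np.arange(0.0, 351.0, 10.0),
    )
    return ef.ensemble_homogeneity(cfg)


class TestHomogeneityCurve:
    def test_normalization_and_envelope(self, small_curve):
        assert small_curve.phi_mean[0] == pytest.approx(1.0, rel=1e-12)
        assert np.all(small_curve.phi_min <= small_curve.phi_mean + 1e-12)
        assert np.all(small_curve.phi_mean <= small_curve.phi_max + 1e-12)

    def test_interior_minimum_shape(self, small_curve):
        # decreases from 1, attains an interior minimum, then increases
        i = int(np.argmin(small_curve.phi_mean))
        assert 0 < i < len(small_curve.chi_grid) - 1
        assert small_curve.phi_mean[i] < 0.5
        assert small_curve.phi_mean[-1] > small_curve.phi_mean[i]
        assert 100.0 < small_curve.chi_star < 320.0

    def test_strip_measure_same_optimum_region(self, embryo, drosophila_flow):
        traj = ef.advect_ensemble(
            drosophila_flow, embryo, 20, 8, 11, np.arange(0.0, 351.0, 10.0)
        )
        kc = traj.kernel_curve(7.0)
        sc = traj.strip_curve(30)
        assert abs(kc.chi_star - sc.chi_star) < 60.0


class TestAmplitude:
    def test_constant_amplitude(self):
        assert ef.chi_from_amplitude(lambda t: 0.3, t=100.0) == pytest.approx(30.0)

    def test_gaussian_total(self):
        gs = ef.GaussianSum(a=(0.2,), b=(500.0,), c=(60.0,))
        assert gs.chi_total() == pytest.approx(0.2 * 60.0 * np.sqrt(2 * np.pi), rel=1e-12)
        assert gs.chi_at(5000.0) == pytest.approx(gs.chi_total(), rel=1e-6)

    def test_tabulated_matches_adaptive_quadrature(self):
        gs = ef.GaussianSum(a=(0.15, 0.3), b=(300.0, 900.0), c=(50.0, 80.0))
        t = np.linspace(0.0, 1400.0, 3000)
        chi_tab = ef.chi_from_amplitude(gs(t), t_samples=t)
        chi_quad, _ = quad(gs, 0.0, 1400.0, limit=200)
        assert chi_tab == pytest.approx(chi_quad, rel=1e-3)

    def test_chi_monotone_in_time(self):
        gs = ef.fixtures.amplitude_preset("wild-type-like")
        ts = np.linspace(0.0, 2000.0, 50)
        chis = [gs.chi_at(t) for t in ts]
        assert np.all(np.diff(chis) >= 0)


class TestGaussianFit:
    def test_three_peak_recovery_with_noise(self):
        true = ef.GaussianSum(a=(0.12, 0.2, 0.3), b=(300.0, 800.0, 1300.0), c=(60.0, 70.0, 80.0))
        t = np.linspace(0.0, 1700.0, 400)
        rng = np.random.default_rng(0)
        v = true(t) * (1.0 + 0.01 * rng.normal(size=t.size))
        fit, err = ef.fit_amplitude_gaussians(t, v, 3)
        assert np.sort(fit.a) == pytest.approx(np.sort(true.a), rel=0.05)
        assert np.sort(fit.b) == pytest.approx(np.sort(true.b), rel=0.05)
        assert np.sort(fit.c) == pytest.approx(np.sort(true.c), rel=0.05)
        assert fit.chi_total() == pytest.approx(true.chi_total(), rel=0.02)
        assert err["chi_total"] < 0.05 * true.chi_total()

    def test_single_clean_gaussian_exact(self):
        true = ef.GaussianSum(a=(0.3,), b=(500.0,), c=(90.0,))
        t = np.linspace(0.0, 1000.0, 300)
        fit, _ = ef.fit_amplitude_gaussians(t, true(t), 1)
        assert fit.a[0] == pytest.approx(0.3, abs=1e-8)
        assert fit.b[0] == pytest.approx(500.0, abs=1e-5)
        assert fit.c[0] == pytest.approx(90.0, abs=1e-5)

    def test_amplitude_rescaling_linearity(self):
        true = ef.GaussianSum(a=(0.1, 0.25), b=(200.0, 700.0), c=(50.0, 60.0))
        t = np.linspace(0.0, 1000.0, 300)
        f1, _ = ef.fit_amplitude_gaussians(t, true(t), 2)
        f2, _ = ef.fit_amplitude_gaussians(t, 3.0 * true(t), 2)
        assert np.sort(f2.a) == pytest.approx(3.0 * np.sort(f1.a), rel=1e-6)
        assert np.sort(f2.b) == pytest.approx(np.sort(f1.b), rel=1e-6)
        assert np.sort(f2.c) == pytest.approx(np.sort(f1.c), rel=1e-6)

    def test_peak_calibration(self):
        true = ef.GaussianSum(a=(0.5, 1.0), b=(200.0, 700.0), c=(50.0, 60.0))
        t = np.linspace(0.0, 1000.0, 300)
        fit, _ = ef.fit_amplitude_gaussians(t, true(t), 2, peak_calibration=0.3)
        assert max(fit.a) == pytest.approx(0.3, rel=1e-8)


class TestDivision:
    def test_coincident_daughters_separate(self, embryo):
        cloud = ef.ParticleCloud(np.zeros((1, 3)), seed=0)
        out = ef.division_spread(cloud, embryo, seed=0)
        assert out.n == 2
        assert np.linalg.norm(out.positions[0] - out.positions[1]) > 1.0

    def test_stays_inside_spheroid(self, embryo):
        cloud = sample_spheroidal_cloud(32, 1, 40.0, 140.0)
        out = ef.division_spread(cloud, embryo, seed=1)
        p = out.positions
        assert np.all((p[:, 0] ** 2 + p[:, 1] ** 2) / embryo.bx**2
                      + p[:, 2] ** 2 / embryo.bz**2 <= 1.0 + 1e-6)

    def test_division_reduces_axial_variance(self, embryo):
        # sign test over an ensemble: with R = 28 um (nuclear separation
        # scale), one division round lowers Phi on average
        zg = np.arange(-embryo.bz, embryo.bz + 0.5, 1.0)
        changes = []
        for s in range(15):
            cloud = sample_spheroidal_cloud(32, 100 + s, 40.0, 140.0)
            before = ef.variance_phi(ef.density(cloud.z, 28.0, zg), zg)
            after_cloud = ef.division_spread(cloud, embryo, seed=200 + s)
            after = ef.variance_phi(ef.density(after_cloud.z, 28.0, zg), zg)
            changes.append((after - before) / before)
        assert np.mean(changes) < 0.0
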