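import numpy as np
import pytest

import embryoflow as ef


@pytest.fixture(scope="session")
def embryo():
    """Reference embryo geometry, bx = 110 um, bz = 270 um."""
    return ef.make_geometry(110.0, 270.0)


@pytest.fixture(scope="session")
def drosophila_profile():
    return ef.fixtures.slip_profile("drosophila")


@pytest.fixture(scope="session")
def drosophila_coeffs(embryo, drosophila_profile):
    """Solved series at the default truncation order."""
    return ef.solve_slip_flow(drosophila_profile, embryo)


@pytest.fixture(scope="session")
def drosophila_flow(drosophila_coeffs):
    return ef.StokesFlowField(drosophila_coeffs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interior_points(g, n, rng, margin=0.98):
    """Uniform random meridional points strictly inside the spheroid."""
    pts = []
    while sum(len(p) for p in pts) < n:
        r = rng.uniform(0.0, g.bx, 2 * n)
        z = rng.uniform(-g.bz, g.bz, 2 * n)
        keep = (r / g.bx) ** 2 + (z / g.bz) ** 2 < margin**2
        pts.append(np.column_stack([r[keep], z[keep]]))
    out = np.concatenate(pts)[:n]
    return out[:, 0], out[:, 1]
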