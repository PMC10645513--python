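"""Long-wavelength flow vs the exact series solution.

The lubrication solution needs no series solve or quadrature — just the
axial wall slip U(z) and the cell radius R(z) — yet reproduces the exact
interior flow to within a few percent for the elongated embryo.
"""

import numpy as np

import embryoflow as ef

g = ef.fixtures.embryo_geometry()
vs = ef.fixtures.slip_profile("drosophila")

lub = ef.LubricationFlowField.for_spheroid(vs, g)
z = 100.0
R = float(g.radius_at(z))
rr = np.linspace(0.0, R, 5)
ur, uz = lub.velocity_rz(rr, np.full_like(rr, z))
print(f"parabolic profile at z={z:.0f} um (R={R:.1f} um):")
for ri, ui in zip(rr, uz):
    print(f"  r={ri:6.1f} um : u_z = {ui:+.3f} um/s")
print("  (wall value equals the axial slip; axis value is its negative;")
print("   zero crossing at r = R/sqrt(2); cross-sectional flux is zero)")

err_uz, err_ur = ef.compare_to_exact(vs, g)
print(f"max error vs exact series: u_z {100*err_uz:.2f}%, u_x {100*err_ur:.2f}% "
      "(normalized by each component's max)")
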