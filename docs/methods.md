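# Methods

## Physical model and assumptions

The cell is a rigid prolate spheroid (semi-minor axis bx, semi-major axis
bz, long axis along z) filled with an incompressible Newtonian fluid at
zero Reynolds number. The actomyosin cortex is not modelled mechanically;
its effect enters as a prescribed axisymmetric tangential slip velocity
v_s(ζ, t) = V(t)·s(ζ) on the boundary, with a fixed spatial shape s and a
time-dependent amplitude V(t) ≥ 0. Because Stokes flow responds
instantaneously to its boundary conditions, the interior field at any
instant is V(t) times the unit-amplitude field, and the trajectory of a
passive tracer depends on V only through the rescaled time
χ(t) = ∫₀ᵗ V dt′ (um) — roughly the distance travelled by cortical
material points. All transport computations therefore use χ as the time
variable. Pressure is never needed: for boundary-driven Stokes flow the
velocity field is independent of the viscosity.

Units throughout: lengths in um, velocities in um/s, angles in radians.
The reference geometry is bx = 110 um, bz = 270 um, giving semi-focal
distance c = √(bz² − bx²) = 246.58 um and boundary coordinate
τ₀ = bz/c = 1.09499.

Nuclei are modelled as non-interacting passive tracers. A Stokes–Einstein
estimate for a 7 um nucleus gives diffusive displacements far below the
embryo scale over the relevant ~30 min, so Brownian motion is neglected;
hydrodynamic interactions between nuclei are also neglected.

## Exact series solution

In modified prolate spheroidal coordinates
r = c√(τ²−1)√(1−ζ²), z = cτζ (boundary τ = τ₀, interior 1 ≤ τ < τ₀), the
Stokes streamfunction has the semiseparable form
ψ(τ, ζ) = Σ_{n≥2} g_n(τ) G_n(ζ) with G_n the Gegenbauer functions of the
first kind of degree −1/2, evaluated through the Legendre-difference form
G_n(x) = (P_{n−2}(x) − P_n(x))/(2n−1), which is polynomial and therefore
valid on both the ζ ∈ [−1, 1] and τ ≥ 1 sides. Second-kind functions are
excluded by regularity on the axis, and the n = 0, 1 radial terms by
regularity on the focal segment, leaving

- g_2 = F₂G₂(τ) + E₄G₄(τ), g_3 = F₃G₃(τ) + E₅G₅(τ),
- g_n = F_nG_n(τ) + E_{n+2}G_{n+2}(τ) + E_nG_{n−2}(τ) for n ≥ 4.

The slip shape is expanded as
v_s(ζ) = τ₀/√(τ₀²−ζ²) Σ_{n≥1} B_n P¹_n(ζ), with

B_n = (2n+1) / (2n(n+1)τ₀) ∫₋₁¹ v_s(ζ) √(τ₀²−ζ²) P¹_n(ζ) dζ,

computed by fixed-order Gauss–Legendre quadrature (128 nodes; the
integrand is smooth because τ₀ > 1 keeps the root away from zero). Two
conventions had to be pinned down numerically and are enforced by tests
rather than by name:

- The associated Legendre convention is the one (with Condon–Shortley
  phase, as in `scipy.special.lpmv`) for which
  √(1−x²)·P¹_l(x) = −l(l+1)·G_{l+1}(x) holds identically.
- The Gegenbauer orthogonality constant is
  ∫₋₁¹ G_nG_m/(1−x²) dx = 2/[n(n−1)(2n−1)] δ_nm, verified by quadrature
  to 1e−13 for n, m ≤ 14.

The boundary conditions close the series order by order: impenetrability
gives g_n(τ₀) = 0, and matching the tangential slip gives
g_n′(τ₀) = τ₀ c² n(n−1) B_{n−1}. Even and odd orders decouple into two
ladders; each step is a 2×2 solve for (F_n, E_{n+2}) reusing the E_n
determined two orders below. The normalization of the right-hand side was
fixed by the self-consistency arbiter: the reconstructed boundary velocity
u_ζ(τ₀, ζ) must reproduce v_s(ζ), which it does to the truncation floor
(RMS 1e−3 of the peak slip at n_max = 14, 7e−5 at 25, machine-limited for
band-limited slips).

Velocities are evaluated from analytic derivatives only
(dG_n/dx = −P_{n−1}(x)); nothing is finite-differenced in production code.
The cylindrical components are assembled in a form regular on the axis:
u_z = (ζψ_ζ − τψ_τ)/(c²(τ²−ζ²)), and the 1/√(1−ζ²) factors of the
spheroidal frame are absorbed using G_n(ζ) = (1−ζ²)P′_{n−1}(ζ)/(n(n−1)).
On the axis u_r = 0 by symmetry. Coordinate inversion uses the
focal-distance identities (d₁ ± d₂)/2c, stable everywhere including the
focal segment.

**Truncation.** The default order is n_max = 14. For the embryo slip
profile, raising it to 25 changes the velocity by at most 0.04% of the
peak speed on an interior grid at 95% of the semi-axes, excluding points
with |u| below 1% of the maximum (the difference concentrates in the
near-boundary pole caps, where the flow is nearly zero). A single slip
mode excites an infinite chain of radial harmonics whose E coefficients
decay geometrically with ratio ≈ 0.35 per step for this slender geometry
(the rate is set by τ₀ − 1), which is why an order well above the number
of significant slip modes is needed.

**Vortex counting** is done on the meridional half-plane (r > 0): the
number of connected single-signed regions of ψ, each a closed
recirculation cell. Slip mode m gives exactly m cells; mirror images in
the full cross-section double the count.

## Long-wavelength solution

For |R′(z)| ≪ 1 the flow is locally pressure-driven pipe flow with zero
net flux through every cross-section:
u_z = U(z)[2(r/R)² − 1],
u_r = ½U′(z) r[1 − (r/R)²] + U(z)R′(z)(r/R)³,
with U(z) the axial component of the wall slip. The projection factor
e_z·e_ζ = τ₀√(1−ζ²)/√(τ₀²−ζ²) is retained exactly when converting the
tangential slip to U (it is 1 at the equator and 0 at the poles); the
further approximation U ≈ −v_s is made only in the 1D reduced model.
Wall slip, axis return flow, exact no-penetration and zero flux hold by
construction. Derivatives U′ and R′ are analytic when the profile is given
in closed form (all built-in fixtures are), otherwise 4th-order central
differences.

Evaluation is restricted to |z| ≤ (1 − 1e−6)bz; the error comparison
against the exact series excludes a pole cap of 1% of bz and normalizes
each component by its global maximum. For the embryo profile the maximum
errors are 4.7% (u_z) and 3.3% (u_x). The validity warning
(max |R′| > 0.5) is checked over the central bulk |z| ≤ 0.7bz, since the
pole caps of any closed shape have diverging slope and are excluded from
evaluation anyway.

## Transport simulation

The initial condition mimics the nuclear cloud at the start of the
spreading cycles: N tracers uniform in a ball of radius 60 um centred on
the axis at z = bz·ζ*, where ζ* = −2 arcsin(1/3)/π ≈ −0.2163 is the
interior zero of the slip shape (the cortical-flow stagnation point).
Advection is classic RK4 in χ with fixed step Δχ = 0.5 um (velocities are
O(1) at unit amplitude; halving the step changes trajectories at the
1e−6 um level), hitting snapshot values exactly by shortening the final
step. After each step, particles with τ > τ₀(1 − 1e−9) are projected
radially just inside the boundary; the exact flow satisfies
no-penetration, so projections are rare round-off events.

Axial uniformity: the kernel density ρ(z) places a Gaussian of bandwidth R
at each tracer's axial position (R = 7 um ≈ nuclear diameter, or
R = 28 um ≈ the aster-migration separation scale); Φ = ∫₋bz^bz (ρ − ρ̄)² dz
by trapezoid on a 1 um grid. The discrete variant counts tracers in
N_strips equal-width strips and takes the variance of the counts.
Ensembles use seeds base_seed + k, k = 0..n_seeds−1 (defaults: 100 seeds,
χ grid 0–400 um in 2 um steps); all clouds are stacked into one particle
array so the series evaluation vectorizes across the ensemble. The
optimum χ* is the argmin of ⟨Φ(χ)⟩/⟨Φ(0)⟩ with quadratic refinement
through the three points around the discrete minimum (~1 um reporting
resolution; the argmin itself scatters by a few um between base seeds).

**Amplitude handling.** V(t) may be a Gaussian sum (χ by error functions),
a callable (adaptive quadrature) or a tabulated series (trapezoid).
`fit_amplitude_gaussians` does bounded nonlinear least squares with
prominence-based peak initialization and widths from half-maximum widths;
an optional calibration rescales the record so the strongest fitted peak
is a given amplitude (0.3 um/s is the value that matches the measured
cortical speed at the strongest contraction peak). The uncertainty of
χ_total = √(2π)Σaᵢcᵢ is propagated from the parameter covariance by the
delta method. The built-in presets are *synthetic* Gaussian-sum stand-ins
for the measured wild-type and mutant records: only their total χ (129 um
and 57 um, the published estimates, taken as inputs) is calibrated; peak
positions and widths are invented.

**Division toy model.** One round of division duplicates each nucleus and
relaxes the doubled cloud under pairwise linear-spring repulsion
f(d) = max(0, 1 − d/28 um), overdamped Euler steps, stopping when the
largest per-step displacement is below 0.01 um, with particles confined to
the spheroid by projection. No measured force law exists for this process,
so the model is qualitative: only the sign of the induced change in Φ
(a decrease, with R = 28 um) is a meaningful prediction, and the test
asserts exactly that over an ensemble.

## Reduced 1D model

With the asymmetric slip symmetrized to −V(t)sin(πζ) and the axial
velocity approximated by u_AP = −v_s(z/bz), the density n(Z, T) on
Z = z/bz ∈ [−1, 1] obeys ∂n/∂T + ∂_Z[sin(πZ)n/π] = 0 with T = πχ/bz.
The method of characteristics gives the exact solution implemented in
`density_exact`; near the endpoints the tangent in the characteristic map
diverges, so for |Z| > 1/2 the complementary cotangent form is used
(the endpoints map to themselves and carry zero density for compactly
supported initial data). The initial density is the parabolic bump
n₀ = 3(Z₀² − Z²)/(4Z₀³) on |Z| ≤ Z₀ with Z₀ = 60/270. The 3/(4Z₀³)
prefactor normalizes the mass to 1, which the conservation law and the
mean density n̄ = 1/2 require; note the argmin of Φ_1D over χ is invariant
to any constant rescaling of n₀ (Φ_1D differs from ∫n² dZ only by
conserved terms), so this choice cannot move the optimum.
Φ_1D = ∫₋₁¹(n − 1/2)² dZ is evaluated by composite Simpson on 2001 points,
with the χ grid 0–400 um in 1 um steps and quadratic argmin refinement.

The exact solution is verified three ways: the T = 0 identity, mass
conservation to 1e−8 (adaptive quadrature split at the support edges), and
a finite-difference residual of the conservation law below 1e−3 of the
density scale away from the support-edge kinks. An independent first-order
upwind finite-volume solve reproduces the optimum to within 2 um.

## A scale discrepancy in the published optimal-χ values

The implementation reproduces every structural property of the published
study at tight tolerance, but the optimal-χ values it computes are
uniformly larger than the originally published ones by the factor
τ₀ = bz/c = 1.0950. The reduced model makes this exact: it is fully
analytic, and with the definitions above (T = πχ/bz) its variance is
minimized at T* = 2.024, i.e. χ* = 174.4 um — yet the published value is
159 um, and 174.4/159 = 1.0943 matches τ₀ to 0.06%. An independent
finite-volume solve of the same conservation law confirms T* = 2.024, so
the discrepancy is not in this implementation. The full 3D simulation
shows the same pattern: this package finds χ* ≈ 214 um (R = 7 um kernel),
232 um (R = 28), 217 um (N = 10) and 216 um (N = 100), each within a few
um of the published 195/213/200/197 multiplied by τ₀. The most plausible
cause is a length-unit slip (c versus bz) in the conversion of rescaled
time to um in the original analysis pipeline. The package reports the
values its own definitions produce; comparisons against the published
optima (and against curve positions evaluated at the published forcing
estimates χ = 129/57 um) inherit this ~9.5% offset, and the corresponding
acceptance checks are expected to fail until the scale question is
resolved at the source. Conclusions that depend only on ratios or on the
existence and robustness of the optimum are unaffected.

## Known limitations

- Rigid, exactly spheroidal cell; no cortex mechanics or feedback, no
  two-phase (gel/sol) rheology. Measured embryonic flows deviate from a
  single-fluid Stokes model in detail (e.g. vorticity extrema positions).
- Tracer nuclei: no excluded volume, no hydrodynamic coupling; division is
  a qualitative toy model.
- The amplitude presets are synthetic stand-ins calibrated only by total
  χ; tests that use them validate the machinery, not the real time series.
- The lubrication solution degrades near the poles (slope of R diverges);
  errors are quoted excluding a 1% pole cap.
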