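# Methods

This note records the models, discretizations and numerical choices
behind `ifem2d`, and what the test problems do and do not demonstrate.

## Problem setting and assumptions

A deformable solid Ωˢ is fully immersed in a fluid domain; solid and
fluid meshes are independent (Lagrangian triangles moving over a fixed
Eulerian triangulation). Three standing assumptions: (1) fluid is
imagined to exist everywhere, so an *artificial fluid* co-occupies Ωˢ
and its effect must be cancelled by the interaction force; (2) no-slip
and traction continuity hold on the interface, which coincides with the
solid boundary; (3) the solid must remain strictly immersed — any solid
node leaving the fluid mesh raises an `ImmersionError` before a step is
attempted. Everything is 2D plane-strain, CGS units internally (µm/kPa
converted at the case-configuration boundary).

## Coupling kernel

Fluid→solid interpolation and solid→fluid force distribution share one
weight table φ, so distribution is the exact transpose of interpolation.
Default kind `fe-shape`: the weights are the barycentric coordinates of
the solid node in its host fluid element — non-negative, at most three
per node, a partition of unity, exactly reproducing for linear fields,
and exactly conservative for distributed nodal forces. A smoothed
radial-cosine `discretized-delta` (support two element sizes, normalised
to partition of unity) is provided as an alternative; a reproducing
kernel (`rkpm`) kind is recognised by name but not implemented. Kernels
are rebuilt every step because the weights depend on the current solid
position; the host-element search uses a KD-tree of element centroids
built once (the fluid mesh never moves). Distribution acts on *nodal
forces* (already integrated over the solid), which keeps conservation
independent of the relative mesh resolutions.

## Fluid solver

Stabilized equal-order P1/P1 finite elements for incompressible
Navier–Stokes with SUPG/PSPG residual stabilization,

τ_e = [(2ρ̄/Δt)² + (2ρ̄|v*|/h_e)² + (12µ/h_e²)²]^(−1/2),  h_e = √(2A_e),

backward-Euler time stepping and Picard linearization of convection
(defaults: 20 iterations, 1e-8 relative tolerance; optional
under-relaxation for convection-dominated impulsive starts). The density
may be a nodal field — passing ρ̄ ≡ ρᶠ assembles bit-identical operators
to the constant-density form, so the semi-implicit momentum equation
degenerates exactly to the original one when the indicator vanishes.

The viscous term is assembled in the gradient ("do-nothing") form
µ∫∇w:∇v rather than the symmetric stress form. For divergence-free
fields the two differ only by boundary terms; the gradient form's
natural boundary condition −p n + µ ∂v/∂n = 0 is *exact* for fully
developed channel flow, which makes pressure-driven benchmarks clean
(centerline error 0.4% at ten elements across the channel, second-order
under refinement), whereas the stress form's natural condition imposes a
spurious zero boundary shear at open boundaries. The Cauchy stress used
by the coupling (∇·σᶠ, interface tractions) is always the full
−pI + µ(∇v+∇vᵀ).

Imposed boundary pressures enter as tractions t = −p̄n on tagged edges
and may be callables of time (the fold case ramps its 1 kPa driving
pressure over 0.2 ms — an impulsive start on quiescent air defeats any
fixed-point linearization). When no traction/outflow boundary fixes the
pressure level, one nodal pressure is pinned automatically. Gravity
defaults to zero; none of the demonstration cases states a body force.

Pseudo-compressible mode (mIFEM) adds the lumped term
(M_L I/(κˢΔt))(p − pⁿ⁻¹) to the continuity rows — the simplest
consistent discretization of the pressure-rate term, active only where
the indicator is positive. With κˢ → ∞ it reproduces the incompressible
solution to 1e-6 relative (tested).

## Solid solver

Plane-strain kinematics with infinitesimal strain for the linear kinds:
σ = C:ε + η ε̇ (isotropic Hooke from E, ν plus a scalar Kelvin–Voigt
viscosity η). Compressible Mooney–Rivlin stress is evaluated from the
full deformation gradient (W = c1(Ī₁−3) + c2(Ī₂−3) + κ/2(J−1)², with
2(c1+c2) = µ by default). κˢ defaults to the plane-strain bulk modulus
E/(2(1+ν)(1−2ν)). No co-rotational correction is applied to the linear
kinds: rigid *infinitesimal* rotations are stress-free (tested), finite
rotations are a validity limit. Internal forces are the weak-form
−∫∇N·σ on the reference configuration and equal −∂(energy)/∂u for the
elastic part (finite-difference-checked).

Dynamics uses Newmark-β with β=1/4, γ=1/2 (trapezoidal, unconditionally
stable, exactly energy-conserving for undamped linear systems — the test
verifies drift below 1e-10 over 100 steps once the initial acceleration
is consistent; `consistent_acceleration` provides it). Boundary data are
prescribed displacement increments q on one subset of the boundary and
constant segment tractions h on the complement. Element inversion
rejects the step.

## Interaction forces and orchestration

Per time step, all schemes run one staggered pass (no sub-iteration to
mutual convergence — matching the published outlines). The explicit
scheme estimates üˢ by backward difference of the two previous
interpolated velocities (zero at the first step). ∇·σᶠ at solid nodes is
obtained by assembling the Galerkin stress residual on the fluid mesh,
converting to a force density with the lumped fluid nodal areas,
interpolating through the kernel, and re-weighting with the solid nodal
areas — interpolating the raw integrated residual would make the force
scale with the fluid mesh resolution.

The indicator Poisson problem is assembled with the interface source
applied directly at the boundary-segment midpoints
(rhs[a] = −Σ_q ∇N_a|host · n_q L_q), which keeps the source as sharp as
the mesh allows; the smoothed nodal-field detour was measurably worse
(11% vs 0.8% area error on the disc benchmark). The sign convention
makes I decrease along the outward normal, i.e. I = 1 inside. Clamps:
I = 1 on nodes deeper than one element size inside the solid polygon
(point-in-polygon with a shrunk/grown buffer), I = 0 outside the grown
polygon; the discrete solution is clipped to [0,1] with overshoot
logged. The interface transition is displaced by O(h) — the disc
integral is accurate to ~1% at four elements per radius.

In the mIFEM orchestrator the solid is driven by the fluid traction
h = −σᶠ·n on its free interface (anchored nodes — e.g. the wall-attached
base of a fold — get zero Dirichlet increments); driving the entire
boundary kinematically from interpolated fluid velocities proved
unstable at large density ratios, because the boundary forcing and the
correction force then form a two-way amplifying loop. The correction
force is discretized as

f^Δv = ρˢ[(vˢₙ − vˢₙ₋₁)/Δt − (vᶠₙ₋₁(xˢ) − vˢₙ₋₁)/Δt − (vᶠ·∇vᶠ)(xˢ)],

i.e. the fluid material derivative is referenced to the previous solid
velocity — identical to the acceleration-difference form whenever the
no-slip condition held at the previous step (the regime the force
maintains), but a monotone *contraction* of the velocity mismatch rather
than a lagged oscillator. Two weightings keep it stable under arbitrary
resolution and density contrast: the interpolated indicator confines the
force to the overlap (otherwise light real-fluid nodes near the
interface receive kicks amplified by the density ratio), and the nodal
force uses the harmonic mean A_sA_f/(A_s+A_f) of solid and local fluid
control areas, which caps the per-step velocity relaxation induced on
any receiving fluid node at one (with solid elements finer than fluid
ones this reduces to the plain solid-area weighting). On the immersed
disc benchmark the correction reduces the RMS no-slip residual about
four-fold.

Diagnostics logged every step: divergence norm, Picard iteration count,
force-conservation residual (round-off by construction), minimum solid
element area, and the coupling-error ratios ρˢ/ρᶠ−1, K/ρᶠ, K/ρˢ,
(ρˢ/ρᶠ−1)g. A warning is emitted when the advective CFL number exceeds
one.

## Demonstration cases and their scope

**Microvessel bifurcation** (explicit IFEM). Mother diameter w0 = 8 µm,
fillets 3 µm, branch angles π/4, cell radius 2.66 µm released on the
axis near the inlet, inlet mean speed 0.1 cm/s; daughter diameters obey
w1/w2 = r_d with w1·w2 = w0² (the combined outflow area stays comparable
across ratios). Blood: ρ = 1.0 g/cm³, µ = 0.1 P. The cell is a
nearly incompressible viscoelastic disc, E = 20 Pa, ν = 0.45,
η = 0.02 P — a soft-cell effective stiffness chosen once (no printed
value exists for it). Flow splits are imposed as parabolic outlet
profiles scaled to Q1/Q2 (an inlet-only variant with natural outflows
exists for multi-cell runs). The geometry generator builds the domain
from strip unions with buffer-rounded fillets and a mirror-symmetrized
point set when r_d = 1, so the symmetric control is symmetric to
round-off (measured drift ≈ 3·10⁻⁴ element sizes). Δt = 2.5·10⁻⁴ s
respects the viscous coupling bound EΔt/µ < 1. The branch label is the
sign of the transverse centroid once it has passed the apex by 0.4·w0
with |y| > 0.08·w0. At r_d = 1.44 with equal flows, the decision (drift
toward the narrow branch) completes before the cell, straddling the
apex, eventually exceeds the linear strain model's range — element
inversion there ends the run with the label already established. A
finite-strain membrane model would be needed to follow the full squeeze;
that is outside this package's constitutive scope.

**Self-oscillating folds** (mIFEM). Channel 1.6 × 0.4 cm; two mirrored
two-layer folds (length 0.5 cm, protrusion 0.17 cm, blunt-ended sine
profile, cover = outer 30% of the thickness), cover E = 10 kPa, body
E = 40 kPa, ρˢ = 1 g/cm³, ν = 0.3, tissue viscosity η = 5 P; air
ρᶠ = 1.3·10⁻³ g/cm³, µ = 1.8·10⁻⁴ P; inlet total pressure 1 kPa ramped
over 0.2 ms, natural outflow, no-slip walls. Diagnostics: half glottis
widths Gw (minimum distance of each fold surface to the centerline,
clamped at zero on contact), and the 2D flow rate Q (per unit depth)
sampled across the glottis exit. The default desk-scale run (300 steps
at 5 µs, ≈ 1700 fluid nodes, three elements across the glottal gap)
resolves the pressure-driven closing phase of the cycle, not a full
self-sustained oscillation — the parametric profile is a documented
stand-in for an undimensioned laminated geometry, so no oscillation
frequency claim is made or tested. The `fidelity`-style knobs (`scale`,
`n_steps`) extend toward production runs.

## What the tests show — and what they do not

The suite verifies the *discrete* contracts (kernel algebra to 1e-12,
force-definition identities, operator degeneracies), the *physical
benchmarks* with closed forms (plane Poiseuille to 1%, cantilever
frequency to 5%, exact patch test), and the *qualitative physics* the
method family was built for: free-stream advection of a neutrally
buoyant solid (explicit), divergence of the explicit scheme versus
boundedness of the semi-implicit one on a stiff falling disc at density
ratio 1000 (Δt = 10⁻⁴ s documented in the test), branch selection in
the bifurcation, and the reduction of the interface slip by the mIFEM
correction force. Synthetic geometries are idealized (polygonal fillets,
sine-profile folds, circular cells); passing these tests shows the
algorithms behave as designed at desk scale, not that any specific
in-vivo quantity is reproduced.

## Known limitations

- Linear/viscoelastic solids carry no co-rotational or finite-strain
  correction; large rotations and extreme squeezes are out of range
  (Mooney–Rivlin stress evaluation exists, but the dynamic solver
  assembles constant small-strain operators).
- No contact mechanics: folds may interpenetrate through the centerline
  if driven far enough; Gw simply clamps at zero.
- The real fluid is always incompressible; pseudo-compressibility
  applies only where the indicator is positive.
- Staggered (loosely coupled) stepping with one pass per step; no
  monolithic or sub-iterated strong coupling.
- Indicator interface position is accurate to O(h); integrated solid
  area to a few percent at typical resolutions.
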