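# Methods

## Physical problem

A drug-eluting stent (DES) holds a curved artery open with a scaffold of
drug-coated struts. Two coupled questions decide its clinical performance:
where the wall shear stress (WSS) is low — low WSS (< 0.5 Pa) marks regions
prone to in-stent restenosis — and how much drug reaches the vascular wall.
Both depend on the flow regime: this package studies a 3 mm lumen bent 90°
at a 10 mm centreline radius, with a 0.5 mm tissue layer, six square
0.10 × 0.10 mm struts over a 15 mm stented arc, and 30 mm straight
extensions, at Reynolds numbers 200–800 (inlet velocities 0.22–0.88 m/s,
blood treated as a Newtonian fluid with ρ = 1055 kg/m³,
μ = 3.5 × 10⁻³ kg/(m·s)).

## Model reduction: the bend-plane surrogate

The full problem is three-dimensional. This package deliberately solves a
desk-scale surrogate: the 2D channel in the plane of the bend (an annular
sector of width d with tissue layers on both sides), which preserves the
inner-bend/outer-bend geometry, the strut-scale flow structures
(recirculation, reattachment) and the conjugate drug transport, at roughly
three orders of magnitude less cost than the 3-million-cell 3D original.
The out-of-plane physics — the Dean secondary circulation — is modelled
separately by the classical fully developed curved-pipe equations on the
circular cross-section (`dean_secondary`).

What the surrogate does *not* capture, and what that implies for the
results:

- **Circumferential drug convection.** In 3D the pair of Dean vortices
  sweeps near-wall fluid from the outer to the inner bend; this is the
  driver of the reported strong inner-bend drug accumulation (Line-A peak
  ratio ≈ 5). The 2D analog has no such sweep: at Re 200 its inner/outer
  peak ratio is close to 1, growing to ≈ 2.7 at Re 800 through the
  inner-bend deceleration near the bend exit. The package reports what the
  2D physics produces; the discrepancy is a property of the reduction, not
  a tunable.
- **WSS sidedness at higher Re.** A fully developed 2D curved channel puts
  the velocity maximum slightly toward the *inner* wall (the streamwise
  pressure gradient per unit arc length is larger at smaller radius), the
  opposite of the secondary-flow-dominated 3D pipe. Consequently the
  inner-bend low-WSS excess seen in 3D holds here only at Re 200 and
  reverses above; trend assertions are limited accordingly.
- **Bend-exit separation at high Re.** Planar bend flow separates on the
  inner wall just downstream of the bend exit once Re is high enough; at
  Re 800 the surrogate develops a ~3 mm low-WSS strip there (s ≈ 45.7–48.4
  mm, right after the bend ends). In the 3D pipe the secondary flow
  re-energizes the inner wall and suppresses this. Consequently the
  *whole-surface* low-WSS percentage is not monotone in Re here
  (3.8/2.9/2.3/3.7% at Re 200–800) even though the stented-segment fraction
  declines monotonically (18.1 → 8.3%).
- Quantities driven by streamwise physics — the decline of wall drug
  concentration with Re, the monotone shrinkage of low-WSS regions over the
  stented segment, the near-linear growth of peak velocity with Re —
  transfer well and are the basis of the acceptance checks.

## Governing equations and discretization

### Flow (`flow_solver`)

Steady incompressible Navier–Stokes with constant properties. The mesh is a
structured orthogonal curvilinear grid in (s, n) — streamwise arc length
and signed transverse offset, metric h = 1 + κ(s)·n — so the equations are
the polar-coordinate momentum equations inside the bend and reduce exactly
to Cartesian form in the extensions. Finite volumes on a staggered (MAC)
arrangement: u on streamwise faces, v on transverse faces, p in cells. The
staggering provides the pressure–velocity decoupling that a collocated
scheme needs momentum interpolation for, with no checkerboard modes and a
simpler correctness argument.

- Convection: first-order upwind implicit plus a deferred second-order
  upwind correction (upstream-slope reconstruction with true spacings).
- Diffusion: second-order two-point fluxes with metric-corrected areas and
  distances; curvature (centrifugal, Coriolis-type and cross-viscous) terms
  appear as cell sources; the decay terms are treated implicitly.
- Wall shear on tangential-velocity equations uses a one-sided quadratic
  gradient (exact for a parabolic profile), so plane Poiseuille flow is
  reproduced to machine precision on any grid.
- Pressure–velocity coupling: SIMPLEC. Momentum systems are relaxed
  implicitly (α_u = 0.8) and solved inexactly by 8 red-black Gauss–Seidel
  sweeps — the outer iterations polish the remainder. The pressure
  correction is solved essentially exactly (BiCGStab preconditioned with a
  periodically refreshed LU factorization, rtol 10⁻¹²), so after every
  outer iteration the face fluxes are discretely divergence-free to
  linear-solver precision; the mass-closure audit is ~10⁻¹⁷ relative.
- Convergence: L1 residuals scaled by their early-iteration maxima,
  threshold 10⁻⁴ (momentum and continuity), as in standard segregated
  practice. Iteration counts at 20 cells/mm run 400–900 per case.
- Boundary conditions: parabolic inlet with mean v_char (centreline
  1.5 v_char — the printed Re–velocity pairs are mutually consistent only
  if the listed velocities are means), zero-pressure outlet with
  extrapolated velocity rescaled to the inlet flux, no-slip on walls and
  strut faces. Struts are blocked cells (solid velocity fixed at zero).

### Drug transport (`drug_transport`)

One steady scalar over lumen + wall: advection–diffusion with k_f = 10⁻⁷
m²/s in blood, pure diffusion with k_t = 10⁻¹² m²/s in tissue. Interface
continuity of concentration and diffusive flux follows from
distance-weighted harmonic face diffusivities (exact for the two-layer
problem, verified to machine precision on the slab fixture). Strut surfaces
carry φ = 1 as a face Dirichlet condition on both lumen- and wall-facing
sides ("full contact"). Advection uses the divergence-free staggered fluxes
of the converged flow; the scheme is implicit upwind plus a minmod-limited
second-order deferred correction iterated on one sparse LU (linear residual
10⁻¹⁰), which keeps φ ∈ [0, 1] at the study's Péclet numbers (up to
~2.6 × 10⁴). The five-decade diffusivity contrast is handled by the direct
factorization. Boundary conditions: φ = 0 at the lumen inlet, zero
streamwise gradient at the outlet, zero flux at the perivascular boundary
and the wall's streamwise ends. A flux audit integrates strut release,
outlet advection and boundary losses; closure is ~10⁻¹⁵ relative.

### Secondary flow (`dean_secondary`)

Fully developed loose-curvature (Dean) equations on the unit disc, stream
function–vorticity form, with the centrifugal source 2 Dn_p² w w_y. The
axial velocity is reported in units of the mean axial velocity, the
secondary stream function in units of ν; the solver matches the flow-rate
Reynolds number (Re = 2 a w̄/ν) by a short outer iteration on the pressure
scale. Numerics that proved necessary at the study's Dean numbers
(77.5–310):

- the wall-vorticity (Thom) closure is coupled *implicitly* with the
  stream-function Poisson equation — the segregated iteration is
  unconditionally unstable on fine grids;
- secondary advection is implicit first-order upwind with face fluxes taken
  as stream-function corner differences (exactly divergence-free);
- the remaining fixed-point map (lagged advecting field and source) is
  wrapped in Anderson(3) acceleration — plain damped Picard limit-cycles
  above Dn ≈ 100 — with continuation in the source strength and a
  step-halving retry on failure.

The leading-order perturbation series
ψ₁ = (Dn²/288) r (1 − r²)² (4 − r²) sin θ (derived by radial ODE solves of
the biharmonic hierarchy; validity documented as Dn ≤ 20) serves as the
independent oracle; the solver agrees within 3.5% at Dn = 10 and
reproduces Hagen–Poiseuille at Dn = 0 to < 0.1%.

### Metrics (`metrics`)

WSS is μ times the one-sided quadratic wall-normal gradient of tangential
velocity on every wetted face: interface faces, strut tops, and strut side
faces (tangential velocity v, streamwise normal). The low-WSS fraction is
arc length below 0.5 Pa over total arc length; the library computes it both
over the stented segment (default, the conservative local measure) and over
the whole wetted wall — the reported percentages in the source study are
taken against the whole model surface, so the acceptance script uses the
whole-wall denominator. Concentration line profiles run 0.25 mm into the
lumen (Line A, |n| = 1.25 mm) and 0.25 mm into the wall (Line B,
|n| = 1.75 mm) on both bend sides, bilinearly interpolated at uniform
spacing over the stented extent; segment statistics split that extent into
equal proximal/middle/distal thirds (the split is not prescribed by the
source; equal thirds chosen).

## Default parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| lumen diameter d | 0.003 | m | study geometry |
| bend radius R | 0.010 | m | study geometry |
| bend angle | 90 | deg | study geometry |
| wall thickness | 0.0005 | m | study geometry |
| stent length / struts | 0.015 / 6 × 0.0001 | m | study geometry; uniform spacing assumed (not stated in the source) |
| extensions | 0.030 | m | flow development |
| ρ, μ | 1055, 3.5e-3 | kg/m³, kg/(m·s) | study constants |
| k_f, k_t | 1e-7, 1e-12 | m²/s | study constants (k_f is used as printed) |
| resolution | 20 | cells/mm | resolves 0.1 mm struts with 2×2 cells and the concentration boundary layer; wall layer ≥ 8 cells |
| residual tol | 1e-4 | — | stated convergence threshold |
| α_u, α_p | 0.8, 0.7 | — | convergence-rate-only choices (no values stated in the source) |
| WSS threshold | 0.5 | Pa | low-WSS definition |
| line offset | 0.25e-3 | m | Line A/B radii 1.25/1.75 mm |

## Problem sizes and verification scope

The default mesh is ≈ 400 × 80 cells (≈ 32 000; 2×2 cells per strut
cross-section); one Reynolds case converges in roughly one minute, the
four-case sweep (warm-started) in 3–4 minutes. The Dean solver uses a
40 × 80 polar grid by default (32 × 64 in the trend tests; the summary
scalars change by well under 1% between the two). Grid convergence of the
headline metrics is checked in the suite between 10 and 20 cells/mm — the
fine end being the study default. The low-WSS fraction is robust (≈ 15%
change for that pair and ≈ 0.4% between 20 and 40 cells/mm). The Line-B
wall-concentration *means* converge slowly (≈ 32% for 10→20, ≈ 12% for
20→40): the near-wall concentration boundary layer at Pe ≈ 6.6 × 10³ and
the strut-contact corners carry a first-order error that a desk-scale mesh
does not exhaust. Ratios of Line-B means across Reynolds numbers — the
quantities the Re-dependence conclusions rest on — are much better
converged, because the shared near-wall bias largely cancels.

Oracles used by the test suite: plane Poiseuille (machine-exact by
construction of the wall flux), the exact fully developed curved-channel
ODE (integrated independently as a boundary-value problem; 2D flow in a
bend has no secondary circulation, so this solution is exact there), the
piecewise-linear two-layer diffusion slab in both the strut-source and
through-flux configurations, and the Dean perturbation series. The
synthetic fixtures emulate geometry and boundary conditions only — they
contain no physiological variability, pulsatility, non-Newtonian rheology
or wall compliance, so passing tests demonstrate correctness of the
discretized model, not clinical fidelity.

## Numerical edge cases and tie-breaks

- Strut cells are flagged by half-open rectangle containment of cell
  centres, making footprints deterministic (2 × 2 cells at the default
  resolution, 48 strut cells).
- A bend angle of zero degenerates cleanly: metric h ≡ 1, Dean number 0,
  "stable" regime.
- The one-column slab fixture exposes its lumen-side boundary as an open
  (Dirichlet-capable) face; transport options `inlet_bc`, `outer_bc`,
  `open_side_value` exist solely for such degenerate configurations.
- Fluxes at faces adjacent to solids are identically zero (staggered
  layout), so the scalar advection operator is conservative and monotone by
  construction; the deferred correction is minmod-limited for the scalar
  and unlimited for momentum.
- The Dean regime threshold is exclusive: Dn = 36 classifies "stable".

## Known limitations

- Steady laminar flow only (solver refuses Re > 2000); no pulsatility, no
  non-Newtonian rheology, no wall elasticity, no transient drug-release
  kinetics or tissue binding — all outside the model by design.
- The 2D surrogate's inner/outer drug-concentration asymmetry is far weaker
  than the 3D secondary-flow-driven value (see above); Line-A ratios from
  this package should be read as qualitative.
- The strut spacing within the stented arc is assumed uniform and struts
  are placed on both bend sides of the plane; the circumferential strut
  pattern of the 3D device is not represented.
- First-order upwinding of the Dean solver's secondary advection slightly
  diffuses the vortices at Dn ≳ 200; summary trends (kinetic energy growth,
  outward shift of the axial maximum) are insensitive to this.
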