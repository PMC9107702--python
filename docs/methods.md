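# Methods

## The model

`pvsporo` simulates CSF/ISF flow around a penetrating cortical arteriole as
an incompressible, finite-deformation biphasic mixture in two subdomains:

* **domain 1** — the fluid-filled spaces: the annular paravascular space
  (PVS) of the penetrating vessel plus the subarachnoid space (SAS), a
  mostly-fluid region (reference fluid fraction ζ_Rf = 0.8) with a very
  soft connective-tissue skeleton (μ_s = 20 Pa);
* **domain 2** — brain parenchyma: extracellular space (ECS) fluid
  fraction 0.2 (0.3 in slow-wave sleep) within a neo-Hookean skeleton of
  shear modulus 2 kPa.

At every point both phases coexist with volume fractions ζ_s + ζ_f = 1.
The formulation is ALE, written on the reference (undeformed-skeleton)
configuration with deformation gradient F = ∇u_s + I, J = det F, and
current fractions ζ_s = ζ_Rs/J.  The fields are the solid displacement
u_s, solid velocity v_s, fluid velocity v_f, filtration velocity
v_flt = ζ_f (v_f − v_s) (the Darcy-flux analogue) and pore pressure p.

Constitutive choices: an isotropic incompressible neo-Hookean skeleton
with stored energy Ψ = μ_s/2 (tr C − 2 ln J) — a "compressible-looking"
form that is legitimate because the *skeleton* compacts by draining fluid,
and convenient because the effective stress vanishes exactly at F = I —
and Darcy–Brinkman fluid rheology: isotropic permeability k_s plus a
Brinkman shear stress with the true fluid viscosity.  The momentum
exchange between phases is the drag (J − ζ_Rs)(μ_f/k_s) v_flt, equal and
opposite in the two phase-momentum equations.  Incompressibility of the
mixture is F^{-T} : ∇(v_s + v_flt) = 0.

At the PVS–parenchyma interface, porosity jumps 0.8 → 0.2.  Displacement,
solid velocity and (both components of) the filtration velocity are
continuous; the total traction is continuous and splits between the phases
in proportion to their volume fractions.  Discretely, u_s and v_flt share
interface degrees of freedom, the pressure space is duplicated per domain
(so p may jump), and the phase-split conditions enter as interface
integrals built from the domain-1 mixture traction operator
P_mix = −J p F^{-T} + P_s + P_f, applied to the parenchyma-side test
functions with a single common normal.  The momentum rows of domain-1 test
functions are dropped on interface nodes (their information enters through
P_mix), which reproduces a uniform-pressure rest state exactly — the
property test that pinned down the sign conventions.

## Discretization and solver

* P2 vector elements for u_s and v_flt, P1 for p (Taylor–Hood-style
  pairing), straight-sided simplices, degree-4 quadrature.
* v_s is the BDF2 time derivative of u_s (backward-Euler bootstrap), and
  v_f is recovered pointwise from the filtration velocity, so the
  five-field model reduces to three discrete fields.
* The pressure gradient is kept in strong (non-integrated) form in the
  momentum equations; with that choice the natural boundary condition of
  the fluid equation is exactly the fluid-phase pressure traction used on
  the open boundaries, and no pressure boundary layer arises.
* Fluid inertia and convection are omitted from the transient solver: the
  Womersley bound ρ_f k_s/(τ μ_f)·10 < 2·10⁻⁵ and |Re| < 10⁻⁴ make them
  irrecoverably small at these scales.  (The pointwise strong-form
  residual API retains every term for verification purposes.)  Solid
  inertia is kept — it costs one mass matrix.
* Each step is solved by a contraction iteration: the neo-Hookean stress
  is linearized consistently (exact tangent μ(δ∇u + F^{-T} δ∇uᵀ F^{-T})),
  while the geometry factors in the drag, Brinkman, pressure and
  constraint terms are refreshed each pass.  Lagging the stress transpose
  term instead (naive Picard) is only marginally stable and was observed
  to diverge slowly; the exact stress tangent makes the iteration
  contractive at all step sizes tested (0.0025–0.1 s).
* Linear systems use a sparse LU factored once per phase and reused as an
  (almost exact) solver, corrected by one to three iterative-refinement
  sweeps per solve; the matrix drifts only with the ~1% geometry changes,
  and refinement is refactored automatically if it stalls.
* The flow-resistance (Robin) outlet at the bottom of the PVS is assembled
  implicitly as a rank-one dissipative block on the facet velocity DOFs.
  With the physiological resistance (2.1·10¹⁷ Pa·s/m³) an explicit lag of
  the flowrate is violently unstable; the implicit block is exact and
  unconditionally stable.

Protocol: a baseline solve ramps the SAS pressure difference (0 → 0.01
mmHg over 0.1 s) and marches until the filtration-velocity change per step
falls below 0.01%; vasodilation transients restart from that state, impose
the wall-motion waveform, and save 201 uniform samples over 10 s.

## Geometry and meshing

The half-domain (symmetry plane x = 0) is 80 × 200 × 200 µm: a 50 µm SAS
channel (z ∈ [150, 200] µm) above parenchyma pierced by the arteriole
(radius 10 µm at the surface tapering to 7.5 µm at z = 0) with an annular
PVS (width 8 → 5.5 µm).  Two deliberate simplifications, both recorded in
the mesh metadata:

* the surface arteriole is modelled as a straight vertical continuation of
  the penetrating vessel through the SAS to the dura (no horizontal sweep
  along y), with the wall-motion amplitude smoothly tapered to zero over
  z ∈ [160, 190] µm below the fixed dura.  The SAS remains an obstructed
  channel and carries the same baseline current; the junction topology is
  simpler and meshable by a single structured O-grid;
* the circular fillet where the PVS opens into the SAS is approximated by
  a 45° chamfer of the same 7 µm extent.

Meshes are block-structured: rays from the vessel axis to the box
boundary (corner directions snapped into the angular grid so outer facets
are exactly planar), radial stations across the PVS and graded through the
parenchyma, Kuhn-split into conforming tetrahedra.  The first parenchyma
layer at the interface is thin (2.5 µm): without it the interface-normal
velocity smears one coarse cell (~15 µm) into the ECS and particle
penetration is grossly overestimated.  Resolution presets: `tiny` (≈0.7k
hexes, 8k unknowns — the suite's desk scale), `desk`, `fine`, and `workstation`
(≈10⁶ unknowns; workstation-scale, hours — the setting at which the
reported three-dimensional reference values are meaningful).

Domain-1 permeability is 2·10⁻¹⁴ m² in the PVS and 2·10⁻¹² m² in the SAS,
blended over z ∈ [130, 150] µm by a quintic smoothstep applied to log₁₀ k
(the permeability spans two decades, so geometric interpolation is the
natural variable).

## Waveforms (the synthetic forcing)

The study conditions prescribe constraints, not closed forms: one dilation
event every 10 s; 2 µm radial amplitude awake (20% of the 20 µm diameter),
4 µm in sleep; the hyperemic pulse reaches peak within 2 s, re-constricts
at about half its peak dilation speed, and carries about twice the
displacement area of the symmetric pulse.  The implementations are a
windowed Gaussian (σ = 0.385 s on a 4 s event) and a gamma-variate
(t/t_p)^α e^{α(1−t/t_p)} with t_p = 1.5 s and α = 4, which lands the
velocity ratio at 0.49 and the AUC ratio at 1.99.  Both are C¹ with
analytic derivatives and exact zeros at the event boundaries; the
constraints are asserted at construction.  Dilation-time sweeps rescale
the pulse in time, so AUC grows linearly with dilation time by
construction.

## Particle tracking

Passive particles are advected in the reference frame,
dX/dt = F⁻¹(v_f − v_s), with finite-element (shape-function) spatial
interpolation and linear interpolation in time between stored samples; the
10 s window is extended periodically to 60 s.  Integration is backward
Euler with fixed-point correction; the default step (half the sampling
interval) changes 60 s occupancy fractions by <1% against further halving.
Classification (PVS/ECS/SAS) uses the reference geometry, since the
advected coordinate is material.  Particles crossing the symmetry plane
are mirrored; particles leaving through open boundaries are frozen, keep
their last region label and are counted separately.  Particles are
passive: water mobility, no diffusion, no size effects.

## Diagnostics

Cross-section flowrates use the deformed-configuration flux
∫ J v_flt · F^{-T} ẑ and the reference area weight ∫ J ζ_Rs (a config flag
switches to the fluid-fraction reading ∫ (J − ζ_Rs); for the PVS the two
differ by the factor 4).  The axial Peclet number is
Pe_a = v̄ L_AV / D_aβ at the PVS bottom (no tortuosity factor); the radial
Peclet field is Pe_r = ⟨v_flt · r̂⟩_t · L_AV / (D_aβ/λ²) on the
parenchyma side of the lateral interface, with amyloid-β diffusivity
D_aβ = 1.4·10⁻⁶ cm²/s, tortuosity λ = 1.6 and L_AV = 150 µm.  Time
averages are taken with signed velocities over the whole window, so purely
oscillatory flow cancels and the averages measure rectification.  These
Peclet numbers are comparison indices against a putative diffusion
process, not flow similarity numbers.

Mass balance: with incompressible constituents the domain volume changes
only through wall motion, so ∮_wall J v_s·F^{-T}n̂ + Σ_open ∮ J
v_flt·F^{-T}n̂ ≈ 0; the worst instantaneous imbalance (relative to the
peak flux) is below 1% in converged runs.

## Verification

* Terzaghi consolidation: the 1D step-load series solution with
  c_v = 2 μ_s k_s/μ_f (confined modulus 2μ_s for this skeleton model);
  pressure profiles agree to <1% at T_v ∈ {0.1, 0.5, 1}.
* Darcy–Brinkman channel: exact rigid-channel profile; max error <1%.
* Manufactured solutions (steady, 2D): observed L2 orders ≈ 3.9 / 2.2 /
  2.0 for u / v_flt / p on meshes n = 8–32 (the filtration velocity
  inherits part of the pressure-gradient error through the Darcy balance,
  so its asymptotic order is set by the P1 pressure, not by P2).
* The 2D lag experiment: displacement forcing with no-slip produces an
  outflow tracking the wall velocity (zero lag); a pressure-like traction
  on both phases produces an outflow whose storage component discharges
  with a consolidation delay.  The lag is quantified as the
  cross-correlation argmax between the forcing-rate waveform and the
  outflow; the ordering lag(pressure) > lag(displacement) holds across a
  40× permeability range.  The block parameters (μ_s = 2 kPa, Gaussian
  pulse σ = 0.3 s) are free choices at the main model's scales.

## What the desk-scale study shows — and what it does not

At the suite's resolution (`tiny`, dt = 0.1 s) every *mechanistic*
statement reproduces: zero lag vs consolidation lag; time-averaged radial
Peclet number twice as large for the asymmetric waveform (ratio 2.01 at
the field level — and the AUC-matched symmetric/asymmetric pair agree in
Pe_r to 0.1%, exactly the area-under-the-dilation-curve collapse the
mechanism predicts); tiny mean axial flow at the PVS bottom; more ECS
penetration asymmetric > symmetric, sleep > awake; ECS penetration
increasing with ECS permeability and with dilation time; similar SAS
escape for both waveforms.  Some particle-level magnitudes are *not* at
the reference workstation-scale values: the asymmetric ECS fraction (23.9%
vs 26.75%) and SAS fraction (5.8% vs 5%) land close, but the symmetric
case penetrates too much (16.5% vs 9%) — coarse interface resolution and
the vertical-vessel simplification overestimate per-event PVS→ECS
exchange, which saturates the occupancy statistics — so the
asymmetric/symmetric fraction ratio compresses to ~1.45 at the 20%
dilation amplitude (it recovers to ~1.9 at 5% dilation, where saturation
is mild), and the AUC-matched pair's *fractions* split even as their Pe_r
fields coincide.  The radial-Peclet maximum itself is sensitive to the
chamfer corner of the approximated junction (values below z = 140 µm are
the geometrically comparable ones) and runs several-fold above the
workstation-scale reference.  The `workstation` preset exists for
workstation-scale reproduction of the reported values; nothing in the desk
runs is calibrated to them.

## Numerical choices and degenerate inputs

* J ≤ 0 or J ≤ ζ_Rs anywhere raises `NonPhysicalStateError` (the fluid
  phase would vanish); converged runs stay far from both.
* Seeds outside the PVS annulus, overlapping waveform events, or a
  waveform violating its shape constraints raise `ValueError` at
  construction.
* The pressure is pinned at one node only in all-Dirichlet verification
  problems; the physical model fixes pressure through the open-boundary
  tractions.
* All tie-breaks (facet tag priority at edges, Dirichlet overlap at
  corners) resolve to the more restrictive constraint; wall motion and the
  fixed-dura condition agree on shared nodes because the amplitude taper
  vanishes there.

## Known limitations

Isotropic permeability, spherical (non-eccentric) PVS, no venular PVS, no
solute diffusion/dispersion (particles are passive), quasi-static fluid
(no heartbeat-band pulsation response), straight vertical vessel, chamfer
in place of the junction fillet, and desk-preset magnitudes as discussed
above.
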