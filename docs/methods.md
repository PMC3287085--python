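# Methods

## Scope and model

`coroflow` simulates pulsatile blood flow through an idealized 2-D left
coronary bifurcation — left main stem (LMS) splitting into left anterior
descending (LAD) and left circumflex (LCx) — with raised-cosine plaques
producing a 60% diameter stenosis at the mid-LMS and proximal LAD, and
reduces the solved fields to the quantities used to characterise the
hemodynamic effect of the plaques: the magnitude of the local spatial
pressure gradient (PSG, kg/(m²·s²) ≡ Pa/m), wall shear stress (WSS, Pa),
cross-section velocity profiles (mm/s), and reversed-flow (recirculation)
fractions, compared across four arms: plaque on/off × Newtonian /
generalized-power-law (GPL) rheology, at peak systole (0.4 s) and
mid-diastole (0.7 s) of a 1.0 s cycle.

Assumptions: incompressible laminar flow; rigid walls and rigid plaque; no
fluid–structure interaction; no side branches beyond LAD/LCx; planar (2-D)
flow. The 2-D domain keeps every mechanism of interest — stenotic
acceleration, post-stenotic deceleration zones, WSS concentration at
throats, PSG amplification — at a problem size that solves in minutes on
one CPU, but absolute field values are not comparable to any 3-D
patient-specific geometry.

## Geometry and meshing

Each branch is a straight centerline with a signed half-width profile
sampled every 0.025 mm. Defaults (typical adult left coronary, all mm):
LMS 4.5 Ø × 10 long; LAD 3.5 Ø × 25; LCx 3.0 Ø × 25; 80° between the
daughters; 1.0 mm junction fillet. The lumen polygon is the union of the
three constant-width strips; reentrant junction corners are rounded by a
morphological closing (dilate–erode by the fillet radius), emulating the
smoothing a segmented patient surface receives. Plaques multiply the local
half-width by f(s) = 1 − (δ/2)(1 + cos(2π(s−s₀)/L)) over |s−s₀| ≤ L/2 — a
C¹ wall with exactly (1−δ)·D minimum diameter — and are carved out of the
filleted polygon; a plaque whose extent overlaps the fillet region is
rejected (the wall is ill-defined there), which is why the default LAD
plaque sits 6 mm from the ostium. Defaults: L = 4 mm, δ = 0.6, symmetric.
An eccentric (one-sided) variant requires δ < 0.5 so the wall cannot cross
the centerline.

Meshing: boundary nodes along the polygon at spacing h, a staggered
near-equilateral interior lattice (h/2 inside a band of ±L around each
plaque), seeded jitter of 0.08 h to avoid co-circular degeneracy, Delaunay
triangulation, and removal of triangles whose centroid leaves the polygon.
Boundary edges on the three end caps are tagged `inlet` / `outlet_lad` /
`outlet_lcx`, the rest `wall`; the tags partition the boundary exactly.
The mesh is a deterministic function of (outline, h, seed). Default
h = 0.25 mm (~8,700 nodes with plaques): chosen so the full four-arm study
completes in roughly five minutes on one CPU, comfortably inside the
documented 15-minute envelope; the channel validation fixtures run at
h = 0.15 mm. Meshes too coarse to put ~3 elements across the narrowest
throat are rejected.

Cross-sections A–O are chords of the actual lumen polygon, perpendicular to
the branch centerline, 0.5 mm apart within each group; A–E bracket the LMS
plaque and F–J the LAD plaque (throats at C and H), K–O sample the proximal
LCx centered at s = 3.5 mm — closer to the ostium the chord runs through
the open junction and is not a genuine branch cross-section.

## Rheology

The GPL constants are interpreted in poise, so the high-shear asymptote
μ∞ = 0.035 poise equals the 0.0035 Pa·s Newtonian viscosity and the two
models coincide at the upper end of the model's stated validity range
(0.1–1000 1/s). Shear rate is γ̇ = sqrt(2 D:D) and is clamped to the
validity window before evaluating the law — the power-law factor diverges
as γ̇ → 0 for n < 1, and the underlying rheometric fit carries no
information outside the window anyway.

## Discretization

Equal-order P1/P1 triangles with a pressure-Laplacian
(Brezzi–Pitkäranta/PSPG-type) stabilization of the continuity equation,
τ_K = 1/(2ρ/Δt + 12 μ_K/h_K²); backward-Euler time stepping at Δt = 12.5 ms
(80 steps per cycle); Picard iterations within each step on the convective
velocity and the apparent-viscosity field, repeated until the normalized
residual falls below 1e-4 (up to 100 iterations, typically 1–2 for
Newtonian and 4–6 for GPL arms). The first of two cycles is discarded as
start-up transient.

Three deliberate numerical choices:

* **Viscous term in gradient (Laplacian) form**, div(μ grad u) rather than
  div(2μD). Its natural boundary condition μ ∂u/∂n − p n = 0 is the
  traction-free outlet and is *exact* for fully developed channel flow
  (the symmetric-gradient form's do-nothing condition distorts Poiseuille
  and Womersley solutions near open boundaries). With spatially varying μ
  this omits the (grad μ)·(grad u)ᵀ term; WSS is computed in
  post-processing from the full velocity gradient and the local rheology,
  not from the solver's stress.
* **Node-projected viscosity.** The element-constant apparent viscosity
  evaluated on P1 shear rates develops an element-scale checkerboard in
  low-shear regions that feeds back through the Picard iteration as a limit
  cycle stalling near residual 3e-4. The discrete viscosity is therefore
  defined as the area-weighted nodal projection of the raw element values,
  averaged back to elements; with it the iteration converges cleanly. The
  residual uses the same definition, so the reported residual is the true
  residual of the discrete system being solved.
* **Factorization reuse.** Each step's first Picard iteration factorizes
  the system (SuperLU); later iterations solve with GMRES preconditioned by
  that factorization (the operator changes little within a step), falling
  back to refactorization if GMRES stalls. A safeguard halves the Picard
  update when the residual grows.

Residual normalization: RMS of the momentum equation residual divided by
the viscous force scale μ_ref·U_ref, and RMS of the continuity residual
divided by the flux scale U_ref·D_ref, with U_ref the waveform's peak mean
velocity and D_ref the inlet width; the reported residual is the maximum of
the three (x-momentum, y-momentum, continuity). The linear-in-U_ref scaling
makes the normalized residual invariant under a uniform rescaling of the
flow state. Because continuity is assembled unintegrated ((q, div u)) and
the stabilization vanishes on constant test functions, global mass
conservation holds to linear-solver precision: inflow matches total outflow
to ~1e-13 relative at every stored step.

Validation oracles (in the test suite): steady plane Poiseuille flow
(profile L2 error < 2%, WSS within 5% of 6μU/h), oscillatory Womersley
channel flow (centerline amplitude and phase within 5% of the analytic
complex solution at the default mesh and timestep), global mass
conservation, cycle-to-cycle periodicity, and bitwise determinism.

## Inlet waveform

The inlet condition is a parabolic profile whose spatial mean follows a
truncated Fourier series (K = 8) fitted to a packaged control-point table.
That table is a synthetic two-feature coronary-like cycle — systolic peak
at 0.40 s, secondary diastolic feature near 0.70 s, period 1.0 s — not a
digitized physiological recording; no tabulated waveform is available to
package. Its amplitude is a single tuning constant set so the spatial-peak
inlet velocity at peak systole is ~17 mm/s, which keeps model velocities in
a 0–37 mm/s band. A user waveform can be supplied as a (t, v) CSV.

## Post-processing

* PSG: element P1 pressure gradients, area-averaged to nodes, Euclidean
  norm. The definition is the *spatial* gradient magnitude; its units
  (kg/m²·s² = Pa/m) identify it as such, and that is how the report header
  documents it.
* WSS: at each wall node the tangential velocity is sampled at distances d
  and 2d along the inward normal (d = 1.2× the local boundary spacing —
  one element row off the wall, past the largest P1 interpolation error);
  with the no-slip zero, γ̇_w = |(4u_t(d) − u_t(2d))/(2d)| is second-order
  accurate and exact for a parabolic profile; WSS = μ(γ̇_w)·γ̇_w with the
  arm's rheology.
* Sections: ≥50 equispaced samples per chord, velocity interpolated
  linearly within elements (points on the exact curved wall are snapped to
  the nearest element within h/4); recirculation fraction = share of
  samples with negative streamwise component.
* Regions for min/max reductions: PSG per branch (nodes assigned to the
  nearest branch axis); WSS over the plaque region (wall nodes within
  ±1.5 plaque lengths of the throat); velocities per section group.
* Throat amplification: ratio of section-mean streamwise velocity at the
  throat plane to a prestenotic reference plane 0.75 plaque lengths
  upstream of the throat. By mass conservation through the 0.4 D throat the
  continuity value is 2.5 for δ = 0.6.

## What the synthetic conditions do and do not show

The study conditions put the throat Reynolds number at roughly 7–15. The
plaque-driven effects that are robust at these desk-scale conditions —
PSG amplification at the stenoses (4–8×), throat velocity amplification at
the continuity value, WSS concentration at the throats, and the
within-factor-2 agreement of Newtonian and GPL WSS there — reproduce the
directional findings of patient-scale studies. Two effects do *not* carry
over to this regime:

* **Post-stenotic recirculation.** The smooth raised-cosine 60% stenosis
  does not separate at these Reynolds numbers: at the two reporting phases
  no reversed streamwise flow exists at the post-plaque sections (verified
  on a 2× finer mesh and with a steady peak-flow solve, where only a
  vestigial ~0.02 mm/s reversal appears in the distal LMS). Transient
  near-wall reversal does occur during post-systolic deceleration
  (t ≈ 0.5 s), but that is a Womersley effect, not plaque-induced
  separation. Recirculation at patient scale rides on an order of magnitude
  higher Reynolds number and eccentric, tortuous lumens.
* **Rheology-independence of WSS away from stenoses.** At these flow rates
  stenosis-free wall shear rates are ~5–25 1/s, where the GPL is ~2× the
  Newtonian viscosity, so plaque-free WSS differs accordingly between the
  models. The asymptotic agreement of the two rheologies is a high-shear
  statement; the suite verifies it in a channel driven at a wall shear rate
  of ~300 1/s (inside the model's validity window), where the wall-WSS
  medians agree within 25%.

Passing tests therefore demonstrate the solver and the pipeline, and the
directional plaque effects listed above — not that this 2-D desk-scale
configuration reproduces patient-specific magnitudes or separation
patterns.

## Other limitations and conventions

* Geometry files are in mm; the solver works in SI; report velocities are
  mm/s, PSG in kg/(m²·s²), WSS in Pa.
* STL export extrudes the planar mesh to 1 mm thickness (watertight by
  construction); binary STL stores float32, so round-trip vertex agreement
  is ~1e-5 mm, not exact.
* Outlets are pseudo-traction-free with equal (zero) reference pressure;
  the LAD:LCx flow split is an outcome of branch resistances, not a
  controlled boundary condition.
* The junction fillet is a morphological closing, so its arcs are
  polygonal (24 segments per quarter circle); cap corner vertices are
  snapped back to their exact positions before meshing.
* No turbulence model, oscillatory-shear indices, time-averaged WSS, or
  3-D effects.
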