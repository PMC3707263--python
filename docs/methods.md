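# Methods

This note records the models, conventions and numerical choices behind
`aaaflow`, and what the test suite does and does not demonstrate.

## Morphometry

The four shape indices are computed from raw vessel measurements in
centimetres: β = r/R, γ = D_max/L_sac, χ = D_max/d_neck, ε = L/τ − 1. γ is
absent (not zero) for a vessel without an identifiable sac, and the
sac-shape label uses a midpoint cut: γ ≥ 0.5 → "saccular", otherwise
"fusiform" (the literature only characterizes the extremes "close to 1" and
"close to 0"; the midpoint is the least surprising deterministic choice,
with the boundary assigned to saccular). Risk flags evaluate the published
cutoffs as printed: D_max > 5.5 cm, β < 0.4, χ > 3.3, γ < 0.6. Note the
γ criterion's direction (low saccular index flagged) sits oddly beside the
association of high γ with spherical sacs; we implement the cutoff as the
source literature states it and leave the epidemiology to the reader.

Measurements with r > R (posterior radius exceeding anterior) are accepted
with a warning and swapped, keeping β ≤ 1 under the posterior/anterior
naming convention. All indices are scale invariant and dimensionless.

## Idealized geometry

`IdealizedAAASpec` describes a single-lumen vessel (units cm):

| parameter | default | meaning |
| --- | --- | --- |
| `neck_radius` | 1.25 | healthy lumen radius (2.5 cm aorta) |
| `max_sac_radius` | 1.9 | symmetric-profile radius at the sac center |
| `sac_length` | 7.0 | exact support of the radial bump |
| `sac_center` | mid-sac | axial position of the bump peak |
| `asymmetry_offset` | 0 | extra anterior-only dilation at the peak |
| `tortuosity_amplitude` | 0 | transverse sinusoid amplitude of the axis |
| `tortuosity_wavelength` | vessel length | one period over the vessel |
| `inlet/outlet_extension` | 6.0 | straight entrance/exit segments |
| `dimension` | 2 | planar (2) or tetrahedral (3) |

The radial bump is cosine-squared — C1-smooth and compactly supported, so
the sac has an exact extent and γ is controllable in closed form. Asymmetry
dilates only the anterior wall (`+asymmetry_offset·bump`); in 3D the
cross-section is a posterior semicircle joined C1 to an anterior
half-ellipse. Tortuosity displaces the centerline laterally by a sinusoid
phase-locked so its slope vanishes at the sac center (midsection planes
stay normal to the axial direction). With radii measured from the healthy
reference axis, β = max_sac_radius/(max_sac_radius + asymmetry_offset),
which spans (0, 1]; no upper bound on the offset is needed for geometric
validity because the posterior wall never moves.

Measurement conventions (both for meshes and for the analytic profile, so
round trips compare like with like):

* the **sac** is the largest axial run where the diameter exceeds 1.05×
  the baseline (proximal-segment median) diameter, with threshold crossings
  interpolated; `L_AAA` is its axial extent;
* `d_proximal_neck` is the baseline diameter itself (using the diameter *at*
  the 1.05 crossing would bias χ by exactly 5%);
* the **reference axis** is the per-station boundary-ring centroid path with
  its anterior component spline-interpolated across the dilated interval —
  the sac shifts ring centroids anteriorly, and the clinical convention
  measures r and R from the hypothetical healthy axis; `L` is the arc length of this
  axis and `τ` its endpoint chord;
* diameters are extents projected onto the plane normal to the local
  centerline tangent (so tilted stations of a tortuous vessel are not
  inflated).

Meshing is deterministic structured extrusion: alternating-diagonal
triangles in 2D (even transverse count preserves mirror symmetry); in 3D a
ring-structured disc (ring k carries 8k nodes, including exact anterior and
posterior nodes) is lofted along the axis and each prism split into three
tetrahedra with a smallest-global-index diagonal rule, giving conforming,
watertight meshes. Element quality is the normalized radius ratio
(dim·r_in/r_circ, 1 for the regular simplex); strongly dilated or sheared
geometries can produce stretched elements, which is warned about (mean
quality is reported; generation only fails on degenerate/inverted
elements). The axial spacing can be set independently of the cross-section
resolution (`axial_edge_length`) — the flow in these vessels varies slowly
axially, and anisotropic extrusion is how the solver stays within desk-scale
budgets.

## Waveforms and boundary conditions

The in-vivo inlet waveform ordinates used in patient studies are not
tabulated, so the package ships an analytic stand-in family: the inlet mean
velocity u(t) is an order-4 Fourier (cosine) truncation of a von-Mises
pulse exp(κ·cos), κ = 4 — one dominant systolic peak exactly at
`peak_time` (default 0.2 s in a 1.0 s cycle; neither is prescribed by the
source protocol beyond the 0.2 s snapshot, both configurable), mild
diastolic flow with a brief weak reversal, peak-to-mean ratio ≈ 4.8. The
outlet pressure is 100 + 20·cos mmHg (80 diastolic to 120 systolic, peak
aligned with systole), converted to Pa. The inlet template has unit peak
amplitude; `calibrate_inflow` rescales it so one cycle carries 500 mL
through the inlet area. In 2D the "area" is per metre of width (h × 1 m),
the package's 2D convention — volumetric calibration is inherently
three-dimensional.

The inlet profile is the fully developed parabola (axial speed
2u(t)(1 − (2r/d)²) in 3D; (3/2)u(t)(1 − (2y/h)²) in 2D so the mean is again
u(t)). The formula's length scale is implemented as the *diameter*: the
profile must vanish at r = d/2 and average to u(t). Viscosity note: blood
viscosity appears in the source literature as 4·10⁻³ Pa·s under both
"kinematic" and "dynamic" names; Pa·s is a dynamic-viscosity unit, so
μ = 4·10⁻³ Pa·s and ν = μ/ρ ≈ 3.81·10⁻⁶ m²/s. With 500 mL/cycle through a
2.5 cm inlet this puts the peak inlet Reynolds number above 10³ (the
package reports Re = U·(4A/P)/ν and asserts nothing about a laminar bound;
the flow is still treated as laminar per the modeling assumption).

## Flow solver

Incremental pressure-correction fractional step on equal-order P1/P1
simplex elements, SI units throughout (cm → m at the mesh boundary):

1. momentum: implicit viscous term, semi-implicit (linearized) convection
   C(uⁿ)u*, old pressure gradient, lumped mass matrix; strong Dirichlet
   inlet/wall rows; direct sparse LU;
2. continuity: pressure-increment Poisson (Δt/ρ)Kφ + stabilization, with
   the outlet waveform imposed as a pressure Dirichlet condition (the
   momentum step leaves the outlet viscous-traction free);
3. projection: u ← u* − (Δt/ρ)M⁻¹Gφ, Dirichlet values re-imposed.

Equal-order interpolation needs pressure stabilization beyond the O(Δt)
splitting term; a Brezzi–Pitkäranta-type pressure Laplacian with
per-element coefficient α·h_K²/μ is added in the continuity step. The
default α = 0.01 was fixed against the closed-form Poiseuille oracles:
α = 0.05 leaves ≈2% mass imbalance and ≈10% pressure-drop error on the
coarse 3D tube, α = 0.01 gives 0.4% and 1.8% while still suppressing
pressure oscillations at the default time steps. Defaults: Δt = T/250 for
pulsatile runs, two cycles (the first sheds the impulsive start), snapshots
stored every 5 steps; a convective-CFL warning is advisory only (the
scheme is implicit). For steady benchmarks the solver marches with frozen
boundary data from a developed initial profile and may refresh the
convection factorization every few steps (Picard reuse; the converged
state satisfies the up-to-date linearization because the final updates use
the settled field).

Per-step diagnostics: inlet/outlet flux (exact P1 facet integration),
their imbalance, an element-divergence residual relative to the velocity
gradient norm, convective CFL, and the per-step velocity increment.

## Post-processing

* **WSS**: per wall facet, μ(∇u + ∇uᵀ)·n̂ from the adjacent element's
  constant gradient, tangential part's magnitude. One-layer gradients are
  first-order at the wall (≈1/n_r bias), which drives the benchmark mesh
  resolutions; superconvergent recovery is a possible extension.
* **Classification**: facets below the area-weighted *sac* mean WSS are
  "low", at-or-above "high" (ties high); with no sac the whole wall sets
  the threshold, with a warning.
* **Recirculation**: fraction of sac volume (area in 2D) where the element
  velocity opposes the local centerline tangent, plus the count of
  face-connected reversed zones. This sign-based definition matches the
  axial-flow framing of vascular CFD and is unambiguous in 2D and 3D.
* **Normalized pressure**: (p − p_min)/(p_max − p_min) over wall nodes; a
  constant field maps to zeros by convention.
* **Snapshot**: all maps are read at the stored stamp nearest to
  (cycles − 1)·T + peak_time; at least two simulated cycles are required.
* **WSS uniformity (CV)**: the coefficient of variation excludes one
  vessel diameter at each axial end — the imposed inlet parabola differs
  from the developed pulsatile (Womersley) profile, and the adjustment band
  is a boundary-condition artifact, not sac physics. With this convention
  the straight control's CV is ≈2% (≈11% including the bands).
* **Cross-sections** at the proximal neck, midsection and distal neck:
  plane/mesh intersection polygons, through-plane and in-plane velocity,
  area centroid vs flux centroid offset (an asymmetry measure).

A finding worth recording: at these desk-scale conditions the idealized 2D
sacs are fully attached at peak systole (accelerating flow); reversed flow
appears during systolic deceleration, in the sac and — as near-wall
Womersley backflow — even in the straight control. Case summaries therefore
report recirculation at the peak-systole protocol stamp *and* at a
mid-deceleration diagnostic stamp (peak_time + 0.4T), where the
geometry-dependence is graded.

## Sweeps and correlations

`run_sweep` varies one spec parameter, collects indices and hemodynamic
scalars per case, and reports Spearman-style rank correlations computed
in-module by sorting (no distributional test claims are attached).
Monotonicity verdicts for the tortuosity sweep (recirculation at both
stamps, neck-region WSS maximum nondecreasing) allow a 1% relative slack
for mesh quantization. The study conditions used by the acceptance suite:
default sac geometry, 2D meshes of ~10⁴ elements, Δt = T/250, two cycles,
tortuosity amplitudes 0/0.75/1.5/2.25 cm (ε up to ≈0.13; larger amplitudes
shear the extruded 2D mesh badly enough to pollute the solution and are
outside the generator's comfortable envelope — a known limitation).

## What the synthetic geometries do and do not show

The generator emulates a single-lumen abdominal aorta with a smooth,
compactly supported sac, anterior-only asymmetry and sinusoidal tortuosity.
It does not reproduce patient lumens: no iliac bifurcation (single outlet),
no intraluminal thrombus, no wall compliance (rigid walls), no
patient-specific waveforms, and 2–2.5 million-element patient meshes are
out of scope. Passing tests demonstrate that the indices, solver and
post-processing are mutually consistent and verified against closed forms
at desk scale — not that patient WSS magnitudes (which depend on the real
CT geometry) are reproduced. Patient-specific WSS statistics are therefore
deliberately absent from the package's outputs.

## Numerical conventions and degenerate inputs

* Benchmark pressure drops are measured between interior stations (central
  half) to exclude entrance/exit perturbations.
* A plane slice coinciding exactly with an extrusion station is nudged by
  1e-7 of the domain extent off the nodes.
* Zero-flow fields give zero WSS, zero recirculation, all-zero normalized
  pressure; degenerate (zero-measure) elements report quality 0 rather
  than raising.
* Mesh generation, solving and post-processing are fully deterministic:
  re-running a config reproduces the summary bitwise. Random seeds appear
  in configs only so external tooling can thread them through.

## Known limitations

First-order wall-gradient WSS; Galerkin convection (no SUPG) limits the
usable cell Reynolds number; structured extrusion cannot follow strongly
sheared or folded lumens; the 2D mode's volumetric calibration is a
per-unit-width convention; the waveform family is a labelled stand-in, not
a measured patient waveform.
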