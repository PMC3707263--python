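# aaaflow

Morphometry and pulsatile hemodynamics of idealized abdominal aortic
aneurysms (AAA).

An infrarenal aortic aneurysm is a pathological dilatation of the abdominal
aorta. Clinical practice gauges rupture risk mostly by the maximum
anteroposterior diameter (5.5 cm threshold), yet small aneurysms rupture and
large ones can stay stable: the *shape* of the sac and the hemodynamic loads
it creates — wall shear stress (WSS), recirculating flow that promotes
intraluminal thrombus — matter as much as its size. `aaaflow` is a desk-scale
laboratory for exploring those geometry–hemodynamics relationships without
patient CT data: it generates parameterized single-lumen aorta geometries
with a controllable sac, solves pulsatile laminar blood flow through them,
and relates the resulting wall shear, pressure and recirculation patterns to
the standard geometric indices.

## The indices and the model

For a vessel with centerline length *L*, endpoint chord *τ*, proximal neck
diameter *d*<sub>neck</sub>, maximum sac diameter *D*<sub>max</sub>, sac
length *L*<sub>sac</sub> and midsection radii *r* (posterior) and *R*
(anterior), the four dimensionless shape indices are

    β = r / R            (asymmetry; 1 = azimuthally symmetric)
    γ = D_max / L_sac    (saccular index; →1 spherical, →0 fusiform)
    χ = D_max / d_neck   (deformation diameter ratio; 1 = non-aneurysmal)
    ε = L / τ − 1        (tortuosity; 0 = straight)

with literature risk flags at `D_max > 5.5 cm`, `β < 0.4`, `χ > 3.3` and
`γ < 0.6`.

Blood is a homogeneous Newtonian fluid (ρ = 1050 kg·m⁻³, μ = 4·10⁻³ Pa·s,
rigid walls). The incompressible Navier–Stokes equations

    ρ(∂u/∂t + (u·∇)u) + ∇p − ∇·(μ∇u) = ρf,   ∇·u = 0

are discretized with equal-order P1/P1 finite elements on simplex meshes and
integrated by an incremental pressure-correction (fractional-step) scheme
with a pressure-Laplacian stabilization. Boundary conditions: no-slip walls,
a fully developed parabolic inlet profile `u_z = 2 u(t) (1 − (2r/d)²)`
driven by a pulsatile template waveform calibrated to carry 500 mL per
cardiac cycle, and a pulsatile normal-traction outlet (80–120 mmHg).
Post-processing extracts the WSS field `μ(∇u + ∇uᵀ)·n̂` (tangential part),
low/high WSS classification against the sac mean, the recirculation fraction
(portion of the sac where flow opposes the centerline direction), normalized
wall pressure, and cross-sections at the proximal neck, midsection and
distal neck — all reported at peak systole (0.2 s) of the second simulated
cycle.

## Worked example

Indices and risk flags from a vessel-measurement table (cm; the shipped
example table uses `;` delimiters and decimal commas):

```bash
$ aaaflow indices src/aaaflow/data/table1.csv
case  ...      chi     beta    gamma  epsilon          shape  flag_asymmetry ...
   1  ... 1.408929 0.608163 0.588806 0.123268       saccular           False
   2  ... 1.421176 0.385057 0.589268 0.029981       saccular            True
   3  ... 1.175385 0.502463 0.340312 0.223303       fusiform           False
   4  ... 1.550385 0.309446 0.258397 0.150004       fusiform            True
   5  ... 1.000000 1.000000      NaN 0.047597 not-applicable           False
```

Case 4 (β ≈ 0.309 < 0.4) raises the asymmetry flag; case 5 is a straight
control aorta (χ = 1, no sac, no flags). Solver verification against the
plane-Poiseuille solution:

```bash
$ aaaflow verify --dimension 2
--- Poiseuille 2D (3840 elements) ---
  u_center_rel_err: 0.00006
  wss_rel_err: 0.02160
  dp_rel_err: 0.00395
  mass_imbalance: 0.00041
  div_rel: 0.00572
--- convergence (2D Poiseuille) ---
  L2 errors: ['0.03449', '0.00878', '0.00220']
  observed orders: ['1.97', '2.00']
```

The centerline velocity, wall shear (6μU/h), pressure gradient (12μU/h²)
and inlet/outlet mass balance all sit within a few percent of the closed
forms, and the velocity error converges at second order. A full pulsatile
case (mesh → two cardiac cycles → summaries, artifacts under `out/`):

```python
from aaaflow import CaseConfig, IdealizedAAASpec, run_case

cfg = CaseConfig(spec=IdealizedAAASpec(dimension=2, tortuosity_amplitude=1.5),
                 outdir="out")
result = run_case(cfg)
print(result.row())
```

which reports the measured indices of the generated lumen plus sac mean/max
WSS (Pa), the neck-region WSS maximum, recirculation fraction, pressure drop
(Pa) and inlet Reynolds number at the peak-systole snapshot. Sweeps over a
geometric parameter (`aaaflow sweep` or `run_sweep`) add rank correlations
between indices and hemodynamic loads and monotonicity verdicts, e.g. that
increasing tortuosity raises neck wall shear and recirculation.

## Layout

| module | contents |
| --- | --- |
| `aaaflow.morphometry` | indices β, γ, χ, ε; shape classification; risk flags |
| `aaaflow.geometry` | parametric idealized lumen (`IdealizedAAASpec`) and its closed-form measurements |
| `aaaflow.meshing` | structured simplex meshing (2D/3D), quality, mesh-based measurement |
| `aaaflow.waveforms` | pulsatile templates, 500 mL calibration, parabolic inlet, Reynolds number |
| `aaaflow.solver` | fractional-step incompressible Navier–Stokes (P1/P1 + stabilization) |
| `aaaflow.postprocess` | WSS, recirculation, normalized pressure, cross-sections, summaries |
| `aaaflow.pipeline` / `aaaflow.cli` | case orchestration, sweeps, reports; `aaaflow` CLI |
| `aaaflow.benchmarks` | analytic Poiseuille/convergence verification suite |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
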