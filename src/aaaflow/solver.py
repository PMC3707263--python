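"""Transient laminar incompressible Newtonian flow on tagged simplex meshes.

The momentum/continuity system

    rho (du/dt + (u.grad) u) + grad p - div(mu grad u) = rho f,   div u = 0

is integrated by an incremental pressure-correction (fractional-step)
scheme on equal-order P1/P1 elements: an implicit-viscous, semi-implicit
(linearized) convection momentum step with the old pressure gradient,
followed by a pressure-increment Poisson solve and a lumped-mass velocity
projection.  Equal-order interpolation is stabilized by a Brezzi-
Pitkaranta-type pressure Laplacian (coefficient ``alpha h_K^2 / mu``) in
the continuity step.

Boundary conditions: strong no-slip on ``wall`` facets, a strong parabolic
profile driven by the inlet waveform on ``inlet`` facets, and the outlet
pressure waveform imposed on ``outlet`` nodes in the pressure step (the
natural momentum condition there is traction-free in the viscous part).
All quantities are SI; blood defaults: rho = 1050 kg/m^3, mu = 4e-3 Pa.s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import P1Basis, apply_dirichlet
from .meshing import SimplexMesh
from .waveforms import InletGeometry, Waveform, parabolic_inlet

__all__ = [
    "FluidProperties",
    "SolverSettings",
    "BCSet",
    "FlowField",
    "SolverError",
    "solve_unsteady",
    "solve_steady",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Constant Newtonian fluid properties (SI units)."""

    density: float = 1050.0        # kg/m^3
    dynamic_viscosity: float = 4e-3  # Pa.s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class SolverSettings:
    """Time-integration and stabilization parameters."""

    dt: float                      # s
    cycles: int = 2
    store_every: int = 5
    stabilization: float = 0.01    # alpha in alpha*h_K^2/mu
    linear_tol: float = 1e-10      # kept for iterative backends; direct LU used
    div_tol: float = 0.1           # advisory relative divergence bound
    cfl_warn: float = 20.0
    conv_update_every: int = 1     # refactor the convection operator every k steps

    def __post_init__(self):
        if self.dt <= 0 or self.cycles < 1 or self.store_every < 1:
            raise ValueError("dt, cycles and store_every must be positive")
        if self.conv_update_every < 1:
            raise ValueError("conv_update_every must be >= 1")
        if self.linear_tol <= 0 or self.div_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class BCSet:
    """No-slip wall, parabolic pulsatile inlet, outlet normal traction."""

    inlet: Waveform                     # mean inlet velocity u(t), m/s
    outlet: Waveform                    # outlet pressure p(t), Pa
    body_force: Tuple[float, ...] = (0.0, 0.0, 0.0)


@dataclass
class FlowField:
    """Stored velocity/pressure snapshots of a transient solve."""

    times: np.ndarray            # (nt,)
    u: np.ndarray                # (nt, n, dim)
    p: np.ndarray                # (nt, n)
    mesh: SimplexMesh
    diagnostics: Dict[str, np.ndarray]  # per-step time, fluxes, residuals

    def at(self, t: float) -> int:
        """Index of the stored snapshot nearest to ``t``."""
        return int(np.argmin(np.abs(self.times - t)))


def _boundary_flux(mesh: SimplexMesh, u: np.ndarray, name: str) -> float:
    """Outward volume flux through a tagged facet set (exact for P1)."""
    mask = mesh.facet_mask(name)
    measures = mesh.facet_measures(mask)
    normals = mesh.facet_normals(mask)
    u_mean = u[mesh.facets[mask]].mean(axis=1)
    return float(np.sum(measures * np.einsum("ij,ij->i", u_mean, normals)))


def _div_norms(basis: P1Basis, u: np.ndarray) -> Tuple[float, float]:
    div = basis.element_divergence(u)
    grad = basis.element_gradient(u)
    div_l2 = math.sqrt(float(np.sum(basis.volumes * div**2)))
    grad_l2 = math.sqrt(float(np.sum(basis.volumes * np.sum(grad**2, axis=(1, 2)))))
    return div_l2, grad_l2


def solve_unsteady(
    mesh: SimplexMesh,
    props: FluidProperties,
    bcs: BCSet,
    settings: SolverSettings,
    initial_u: Optional[np.ndarray] = None,
    t_end: Optional[float] = None,
    steady_tol: Optional[float] = None,
) -> FlowField:
    """Run ``settings.cycles`` cardiac cycles of the fractional-step scheme.

    Snapshots are stored every ``settings.store_every`` steps (plus the
    final state).  ``steady_tol`` turns the run into a steady march that
    stops early once the relative velocity increment per step falls below
    the tolerance.  Raises :class:`SolverError` on linear-solver breakdown
    and warns (advisory only, the scheme is implicit) when the convective
    CFL number exceeds ``settings.cfl_warn``.
    """
    dim = mesh.dim
    n = mesh.npoints
    rho, mu = props.density, props.dynamic_viscosity
    dt = settings.dt
    T = bcs.inlet.period
    n_steps_cycle = int(round(T / dt))
    if abs(n_steps_cycle * dt - T) > 1e-9 * T:
        raise ValueError("dt must divide the waveform period")
    total_time = t_end if t_end is not None else settings.cycles * T
    n_steps = int(round(total_time / dt))

    basis = P1Basis(mesh)
    K = basis.stiffness()
    ML = basis.lumped_mass()
    G = basis.gradient_ops()
    inlet_geom = InletGeometry.from_mesh(mesh)

    wall_nodes = mesh.facet_nodes("wall")
    inlet_nodes = mesh.facet_nodes("inlet")
    outlet_nodes = mesh.facet_nodes("outlet")
    # a node on both wall and inlet rims is no-slip (profile vanishes there)
    dirichlet = np.unique(np.concatenate([wall_nodes, inlet_nodes]))

    # pressure system: (dt/rho) K + BP stabilization, outlet Dirichlet
    h2w = settings.stabilization * basis.h_elem**2 / mu
    K_stab = basis.stiffness(weight=h2w)
    Ap = (dt / rho) * K + K_stab
    Ap_bc = apply_dirichlet(Ap, outlet_nodes)
    try:
        lu_p = spla.splu(Ap_bc.tocsc())
    except RuntimeError as exc:  # pragma: no cover
        raise SolverError(f"pressure operator factorization failed: {exc}")

    u = np.zeros((n, dim))
    inlet_pts = mesh.points[inlet_nodes]
    u[inlet_nodes] = parabolic_inlet(inlet_pts, 0.0, bcs.inlet, inlet_geom)
    u[wall_nodes] = 0.0
    if initial_u is not None:
        u = initial_u.copy()
        u[wall_nodes] = 0.0
        u[inlet_nodes] = parabolic_inlet(inlet_pts, 0.0, bcs.inlet, inlet_geom)
    p = np.full(n, float(bcs.outlet(0.0)))

    f = np.asarray(bcs.body_force[:dim], dtype=float)

    times: List[float] = [0.0]
    stored_u = [u.copy()]
    stored_p = [p.copy()]
    diag = {k: [] for k in
            ("time", "inlet_flux", "outlet_flux", "mass_imbalance",
             "div_rel", "cfl", "delta_u_rel")}

    cfl_warned = False
    for step in range(1, n_steps + 1):
        t1 = step * dt

        speeds = np.linalg.norm(u[mesh.elements].mean(axis=1), axis=1)
        cfl = float(np.max(speeds / basis.h_elem)) * dt
        if cfl > settings.cfl_warn and not cfl_warned:
            warnings.warn(
                f"convective CFL {cfl:.1f} exceeds advisory bound "
                f"{settings.cfl_warn} at step {step} (implicit scheme, "
                "accuracy may degrade)"
            )
            cfl_warned = True

        if step == 1 or (step - 1) % settings.conv_update_every == 0:
            C = basis.convection(u)
            A = sp.diags(rho / dt * ML) + rho * C + mu * K
            A_bc = apply_dirichlet(A.tocsr(), dirichlet)
            try:
                lu_m = spla.splu(A_bc.tocsc())
            except RuntimeError as exc:
                raise SolverError(
                    f"momentum factorization failed at step {step}: {exc}"
                )

        u_in = parabolic_inlet(inlet_pts, t1, bcs.inlet, inlet_geom)
        u_star = np.empty_like(u)
        for c in range(dim):
            rhs = rho / dt * ML * u[:, c] - G[c] @ p + rho * f[c] * ML
            rhs[dirichlet] = 0.0
            rhs[inlet_nodes] = u_in[:, c]
            sol = lu_m.solve(rhs)
            if not np.all(np.isfinite(sol)):
                raise SolverError(f"momentum solve diverged at step {step}")
            u_star[:, c] = sol

        rhs_p = -basis.divergence(u_star, G) - K_stab @ p
        rhs_p[outlet_nodes] = float(bcs.outlet(t1)) - p[outlet_nodes]
        phi = lu_p.solve(rhs_p)
        if not np.all(np.isfinite(phi)):
            raise SolverError(f"pressure solve diverged at step {step}")
        p = p + phi

        u_new = u_star.copy()
        for c in range(dim):
            u_new[:, c] -= (dt / rho) * (G[c] @ phi) / ML
        u_new[wall_nodes] = 0.0
        u_new[inlet_nodes] = u_in

        delta = float(np.max(np.abs(u_new - u)) / max(np.max(np.abs(u_new)), 1e-300))
        u = u_new

        q_in = _boundary_flux(mesh, u, "inlet")
        q_out = _boundary_flux(mesh, u, "outlet")
        div_l2, grad_l2 = _div_norms(basis, u)
        diag["time"].append(t1)
        diag["inlet_flux"].append(q_in)
        diag["outlet_flux"].append(q_out)
        diag["mass_imbalance"].append(
            abs(q_in + q_out) / max(abs(q_in), 1e-300)
        )
        diag["div_rel"].append(div_l2 / max(grad_l2, 1e-300))
        diag["cfl"].append(cfl)
        diag["delta_u_rel"].append(delta)

        if step % settings.store_every == 0 or step == n_steps:
            times.append(t1)
            stored_u.append(u.copy())
            stored_p.append(p.copy())

        if steady_tol is not None and delta < steady_tol:
            if times[-1] != t1:
                times.append(t1)
                stored_u.append(u.copy())
                stored_p.append(p.copy())
            break

    return FlowField(
        times=np.asarray(times),
        u=np.asarray(stored_u),
        p=np.asarray(stored_p),
        mesh=mesh,
        diagnostics={k: np.asarray(v) for k, v in diag.items()},
    )


def solve_steady(
    mesh: SimplexMesh,
    props: FluidProperties,
    mean_velocity: float,
    outlet_pressure: float = 0.0,
    dt: Optional[float] = None,
    max_steps: int = 400,
    tol: float = 1e-8,
    stabilization: float = 0.01,
    developed_start: bool = True,
    conv_update_every: int = 5,
) -> FlowField:
    """March a constant-inflow problem to steady state.

    The inlet carries the parabolic profile with constant mean
    ``mean_velocity``; the march starts from the developed profile
    replicated along the vessel (unless ``developed_start`` is False) and
    stops once the per-step relative velocity increment drops below
    ``tol``.
    """
    inlet_geom = InletGeometry.from_mesh(mesh)
    length = float(mesh.points[:, 0].max() - mesh.points[:, 0].min())
    if dt is None:
        dt = 0.25 * length / max(mean_velocity, 1e-12)
    period = dt * max_steps * 4.0  # pseudo period, never completed
    w_in = Waveform(period=period, peak_time=period / 2,
                    coeffs=(1.0,), amplitude=mean_velocity, name="steady-inlet")
    w_out = Waveform(period=period, peak_time=period / 2,
                     coeffs=(1.0,), amplitude=outlet_pressure, name="steady-outlet")
    settings = SolverSettings(dt=dt, cycles=1, store_every=max_steps,
                              stabilization=stabilization,
                              conv_update_every=conv_update_every)
    initial = None
    if developed_start:
        pts = mesh.points
        initial = parabolic_inlet(
            pts - np.outer(pts @ inlet_geom.axis, inlet_geom.axis)
            + np.outer(np.full(len(pts), inlet_geom.center @ inlet_geom.axis),
                       inlet_geom.axis),
            0.0, w_in, inlet_geom,
        )
    bcs = BCSet(inlet=w_in, outlet=w_out)
    return solve_unsteady(
        mesh, props, bcs, settings,
        initial_u=initial, t_end=max_steps * dt, steady_tol=tol,
    )
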