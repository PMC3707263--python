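"""Analytic verification benchmarks for the flow solver.

Every benchmark compares a steady solve on a straight vessel against the
corresponding closed-form laminar solution:

* plane Poiseuille (2D channel): centerline speed 1.5 U, wall shear
  6 mu U / h, pressure gradient 12 mu U / h^2;
* Hagen-Poiseuille (3D circular tube): centerline 2 U, wall shear
  8 mu U / D, pressure drop 8 mu L Q / (pi R^4);
* discrete inlet/outlet mass balance;
* spatial convergence of the velocity L2 error under uniform refinement.

Pressure drops are measured between two interior stations inside the
fully developed region (the first and last half-centimetre carry
entrance/exit perturbations of the discrete profile).
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, Optional

import numpy as np

from .geometry import IdealizedAAASpec
from .meshing import generate_mesh
from .postprocess import compute_wss
from .solver import FlowField, FluidProperties, solve_steady

__all__ = [
    "poiseuille_benchmark",
    "convergence_study",
    "BENCH_SPEC_2D",
    "BENCH_SPEC_3D",
]

#: short straight vessels used by the verification suite (lengths in cm)
BENCH_SPEC_2D = IdealizedAAASpec(
    dimension=2, inlet_extension=2.0, outlet_extension=2.0, sac_length=2.0
).straight()
BENCH_SPEC_3D = IdealizedAAASpec(
    dimension=3, inlet_extension=2.0, outlet_extension=2.0, sac_length=2.0
).straight()


def _station_pressure(mesh, p: np.ndarray, z: float):
    zs = np.round(mesh.points[:, 0], 12)
    stations = np.unique(zs)
    zn = stations[np.argmin(np.abs(stations - z))]
    return float(p[zs == zn].mean()), float(zn)


def poiseuille_benchmark(
    dimension: int = 2,
    mean_velocity: float = 0.1,
    edge_length: Optional[float] = None,
    axial_edge_length: Optional[float] = None,
    props: FluidProperties = FluidProperties(),
    max_steps: int = 400,
    tol: float = 1e-9,
) -> Dict[str, float]:
    """Run the steady Poiseuille verification case; return measured vs
    exact values and their relative errors."""
    if dimension == 2:
        spec = BENCH_SPEC_2D
        edge = 0.0625 if edge_length is None else edge_length
        hz = 0.125 if axial_edge_length is None else axial_edge_length
        U = mean_velocity
    else:
        spec = BENCH_SPEC_3D
        edge = 0.104 if edge_length is None else edge_length
        hz = 0.25 if axial_edge_length is None else axial_edge_length
        U = mean_velocity / 2.0  # keep the tube Reynolds number moderate
    mesh = generate_mesh(spec, edge, axial_edge_length=hz)
    field = solve_steady(mesh, props, U, tol=tol, max_steps=max_steps)
    u = field.u[-1]
    p = field.p[-1]
    mu = props.dynamic_viscosity

    h = 2.0 * spec.neck_radius * 0.01       # m (channel height / tube diameter)
    pts = mesh.points
    z_lo, z_hi = pts[:, 0].min(), pts[:, 0].max()
    z_mid = 0.5 * (z_lo + z_hi)

    # centerline velocity at mid-length
    radial = np.abs(pts[:, 1]) if dimension == 2 else np.hypot(pts[:, 1], pts[:, 2])
    node = int(np.argmin(np.abs(pts[:, 0] - z_mid) + radial))
    u_center = float(u[node, 0])
    u_center_exact = (1.5 if dimension == 2 else 2.0) * U

    # wall shear over the central band
    wss = compute_wss(field, mesh, props, field.times[-1])
    band = (wss.centroids[:, 0] > z_lo + 0.25 * (z_hi - z_lo)) & (
        wss.centroids[:, 0] < z_hi - 0.25 * (z_hi - z_lo)
    )
    wss_med = float(np.median(wss.values[band]))
    wss_exact = 6.0 * mu * U / h if dimension == 2 else 8.0 * mu * U / h

    # pressure drop between interior stations (developed region)
    p1, z1 = _station_pressure(mesh, p, z_lo + 0.25 * (z_hi - z_lo))
    p2, z2 = _station_pressure(mesh, p, z_hi - 0.25 * (z_hi - z_lo))
    length = z2 - z1
    if dimension == 2:
        dp_exact = 12.0 * mu * U * length / h**2
    else:
        R = h / 2.0
        Q = U * math.pi * R**2
        dp_exact = 8.0 * mu * length * Q / (math.pi * R**4)
    dp = p1 - p2

    d = field.diagnostics
    wall_nodes = mesh.facet_nodes("wall")
    wall_speed = float(np.max(np.linalg.norm(u[wall_nodes], axis=1)))
    return {
        "dimension": dimension,
        "elements": mesh.nelements,
        "u_center": u_center,
        "u_center_exact": u_center_exact,
        "u_center_rel_err": abs(u_center - u_center_exact) / u_center_exact,
        "wss": wss_med,
        "wss_exact": wss_exact,
        "wss_rel_err": abs(wss_med - wss_exact) / wss_exact,
        "dp": dp,
        "dp_exact": dp_exact,
        "dp_rel_err": abs(dp - dp_exact) / dp_exact,
        "mass_imbalance": float(d["mass_imbalance"][-1]),
        "div_rel": float(d["div_rel"][-1]),
        "max_wall_speed_rel": wall_speed / max(u_center, 1e-300),
        "steps": len(d["time"]),
    }


def _l2_error_2d(mesh, u: np.ndarray, U: float, h: float) -> float:
    """Relative velocity L2 error against the plane-Poiseuille profile,
    by edge-midpoint quadrature (exact for quadratics)."""
    pts = mesh.points
    elems = mesh.elements
    x = pts[elems]
    vols = np.abs(
        (x[:, 1, 0] - x[:, 0, 0]) * (x[:, 2, 1] - x[:, 0, 1])
        - (x[:, 1, 1] - x[:, 0, 1]) * (x[:, 2, 0] - x[:, 0, 0])
    ) / 2.0

    def exact(y):
        return 1.5 * U * (1.0 - (2.0 * y / h) ** 2)

    err2 = np.zeros(len(elems))
    ref2 = np.zeros(len(elems))
    for (i, j) in ((0, 1), (1, 2), (0, 2)):
        mid = 0.5 * (x[:, i, :] + x[:, j, :])
        uh = 0.5 * (u[elems[:, i]] + u[elems[:, j]])
        ue = np.stack([exact(mid[:, 1]), np.zeros(len(mid))], axis=1)
        err2 += np.sum((uh - ue) ** 2, axis=1) / 3.0
        ref2 += np.sum(ue**2, axis=1) / 3.0
    return math.sqrt(float(np.sum(vols * err2))) / math.sqrt(float(np.sum(vols * ref2)))


def convergence_study(
    refinements=(6, 12, 24),
    mean_velocity: float = 0.1,
    props: FluidProperties = FluidProperties(),
) -> Dict[str, list]:
    """Velocity L2 error of the steady 2D Poiseuille solve over uniform
    refinements; the observed order should approach 2."""
    spec = BENCH_SPEC_2D
    h_channel = 2.0 * spec.neck_radius * 0.01
    errors = []
    spacings = []
    counts = []
    for ny in refinements:
        edge = 2.0 * spec.neck_radius / ny
        mesh = generate_mesh(spec, edge, axial_edge_length=edge)
        field = solve_steady(mesh, props, mean_velocity, tol=1e-10, max_steps=600)
        errors.append(_l2_error_2d(mesh, field.u[-1], mean_velocity, h_channel))
        spacings.append(edge)
        counts.append(mesh.nelements)
    orders = [
        math.log(errors[k] / errors[k + 1]) / math.log(spacings[k] / spacings[k + 1])
        for k in range(len(errors) - 1)
    ]
    return {
        "spacings_cm": spacings,
        "elements": counts,
        "l2_errors": errors,
        "orders": orders,
    }
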