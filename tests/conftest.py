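"""Shared fixtures: small meshes and cached solves (built once per session)."""

import numpy as np
import pytest

from aaaflow.geometry import IdealizedAAASpec
from aaaflow.meshing import generate_mesh
from aaaflow.solver import (
    BCSet,
    FluidProperties,
    SolverSettings,
    solve_steady,
    solve_unsteady,
)
from aaaflow.waveforms import InletGeometry, calibrate_inflow, template_waveforms


@pytest.fixture(scope="session")
def props():
    return FluidProperties()


@pytest.fixture(scope="session")
def channel_spec():
    return IdealizedAAASpec(
        dimension=2, inlet_extension=2.0, outlet_extension=2.0, sac_length=2.0
    ).straight()


@pytest.fixture(scope="session")
def channel_mesh(channel_spec):
    """Moderate 2D channel (20 cells across)."""
    return generate_mesh(channel_spec, 0.125, axial_edge_length=0.2)


@pytest.fixture(scope="session")
def channel_steady(channel_mesh, props):
    """Steady plane-Poiseuille solve, mean velocity 0.1 m/s."""
    return solve_steady(channel_mesh, props, 0.1, tol=1e-9, max_steps=300)


@pytest.fixture(scope="session")
def sac_run(props):
    """Short pulsatile run on a small 2D aneurysmal geometry."""
    spec = IdealizedAAASpec(dimension=2)
    mesh = generate_mesh(spec, 0.18, axial_edge_length=0.3)
    from aaaflow.meshing import measure_geometry

    meas, details = measure_geometry(mesh, return_details=True)
    w_in, w_out = template_waveforms(1.0, 0.2)
    geom = InletGeometry.from_mesh(mesh)
    w_in = calibrate_inflow(w_in, geom.area, 500e-6)
    settings = SolverSettings(dt=0.01, cycles=2, store_every=10)
    field = solve_unsteady(mesh, props, BCSet(inlet=w_in, outlet=w_out), settings)
    return {
        "spec": spec,
        "mesh": mesh,
        "measurements": meas,
        "details": details,
        "inlet_waveform": w_in,
        "outlet_waveform": w_out,
        "field": field,
    }
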