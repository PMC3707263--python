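"""Idealized geometry generation, meshing, measurement and file round trip."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from aaaflow import io as mesh_io
from aaaflow.geometry import (
    IdealizedAAASpec,
    amplitude_for_epsilon,
    analytic_measurements,
    bump,
    implied_indices,
    offset_for_beta,
    radius_profile,
)
from aaaflow.meshing import (
    MeshGenerationError,
    SimplexMesh,
    generate_mesh,
    is_watertight,
    measure_geometry,
    mesh_quality,
)
from aaaflow.morphometry import compute_indices


# ---------------------------------------------------------------------------
# radius profile / analytic spec
# ---------------------------------------------------------------------------

def test_degenerate_bump_gives_straight_tube():
    spec = IdealizedAAASpec(max_sac_radius=1.25, neck_radius=1.25,
                            asymmetry_offset=0.0)
    z = np.linspace(0, spec.total_length, 50)
    post, ant = radius_profile(spec, z)
    assert np.allclose(post, 1.25) and np.allclose(ant, 1.25)


def test_bump_peak_offset_equals_asymmetry_offset():
    spec = IdealizedAAASpec(asymmetry_offset=0.96)
    post, ant = radius_profile(spec, spec.sac_center_)
    assert ant - post == pytest.approx(0.96, rel=1e-12)
    assert post == pytest.approx(spec.max_sac_radius)


def test_radius_profile_domain_error():
    spec = IdealizedAAASpec()
    with pytest.raises(ValueError, match="axial"):
        radius_profile(spec, spec.total_length + 1.0)


def test_spec_validation():
    with pytest.raises(ValueError):
        IdealizedAAASpec(max_sac_radius=1.0, neck_radius=1.25)
    with pytest.raises(ValueError):
        IdealizedAAASpec(asymmetry_offset=-0.5)
    with pytest.raises(ValueError):
        IdealizedAAASpec(dimension=4)


def test_bump_is_compactly_supported():
    spec = IdealizedAAASpec()
    zc, half = spec.sac_center_, spec.sac_length / 2
    assert bump(spec, zc) == pytest.approx(1.0)
    assert bump(spec, zc - half - 1e-9) == 0.0
    assert bump(spec, zc + half + 1e-9) == 0.0


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dimension", [2, 3])
def test_generated_mesh_is_watertight_and_tagged(dimension):
    spec = IdealizedAAASpec(dimension=dimension, asymmetry_offset=0.5)
    mesh = generate_mesh(spec, 0.3)
    assert is_watertight(mesh)
    assert np.all(mesh.element_volumes() > 0)
    for name in ("inlet", "outlet", "wall"):
        assert np.any(mesh.facet_mask(name))
    # inlet and outlet are planar and disjoint from the wall facets
    for name, z in (("inlet", 0.0), ("outlet", spec.total_length * 0.01)):
        nodes = mesh.facet_nodes(name)
        assert np.allclose(mesh.points[nodes, 0], z, atol=1e-12)


def test_inlet_area_matches_analytic():
    spec = IdealizedAAASpec(dimension=3).straight()
    mesh = generate_mesh(spec, 0.1, axial_edge_length=0.5)
    area = float(mesh.facet_measures(mesh.facet_mask("inlet")).sum())
    assert area == pytest.approx(np.pi * 0.0125**2, rel=0.01)


@pytest.mark.parametrize("dimension", [2, 3])
def test_halving_edge_length_scales_element_count(dimension):
    spec = IdealizedAAASpec(
        dimension=dimension, inlet_extension=2, outlet_extension=2, sac_length=2
    ).straight()
    coarse = generate_mesh(spec, 0.4)
    fine = generate_mesh(spec, 0.2)
    ratio = fine.nelements / coarse.nelements
    assert ratio == pytest.approx(2.0**dimension, rel=0.25)


def test_edge_length_must_resolve_neck():
    with pytest.raises(MeshGenerationError):
        generate_mesh(IdealizedAAASpec(), 2.0)


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def test_quality_anchors():
    eq = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    tris = np.array([[0, 1, 2]])
    assert mesh_quality(eq, tris)["per_element"][0] == pytest.approx(1.0, abs=1e-12)
    needle = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.0005]])
    assert mesh_quality(needle, tris)["per_element"][0] < 0.01


def test_regular_tetrahedron_quality_is_one():
    pts = np.array([
        [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]
    ])
    q = mesh_quality(pts, np.array([[0, 1, 2, 3]]))
    assert q["per_element"][0] == pytest.approx(1.0, abs=1e-9)


def test_straight_tube_mesh_quality_floor():
    # empirical floors of the structured generator, frozen
    q2 = mesh_quality(generate_mesh(IdealizedAAASpec(dimension=2).straight(), 0.25))
    assert q2["mean"] >= 0.8
    q3 = mesh_quality(generate_mesh(IdealizedAAASpec(dimension=3).straight(), 0.25))
    assert q3["mean"] >= 0.65


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def test_straight_tube_measurements():
    spec = IdealizedAAASpec(dimension=2).straight()
    m = measure_geometry(generate_mesh(spec, 0.2))
    assert m.D_AMAX == pytest.approx(2.5, rel=1e-9)
    assert m.L_AAA is None
    assert m.L - m.tau < 1e-6 * m.tau
    assert compute_indices(m).chi == pytest.approx(1.0, rel=1e-9)


def test_mirror_symmetric_spec_measures_equal_radii():
    spec = IdealizedAAASpec(dimension=2, asymmetry_offset=0.0,
                            tortuosity_amplitude=0.0)
    m = measure_geometry(generate_mesh(spec, 0.15))
    assert m.r == pytest.approx(m.R, rel=1e-9)


def test_case_like_round_trip_2pct():
    """Spec tuned near Table-1 case 1 indices: measured back within 2%."""
    spec = IdealizedAAASpec(
        dimension=3, neck_radius=1.4, max_sac_radius=1.9,
        sac_length=6.7, asymmetry_offset=1.2, tortuosity_amplitude=2.0,
    )
    mesh = generate_mesh(spec, 0.2)
    got = compute_indices(measure_geometry(mesh))
    want = implied_indices(spec)
    assert got.beta == pytest.approx(want.beta, rel=0.02)
    assert got.gamma == pytest.approx(want.gamma, rel=0.02)
    assert got.chi == pytest.approx(want.chi, rel=0.02)
    assert got.epsilon == pytest.approx(want.epsilon, rel=0.02, abs=1e-4)


def test_asymmetric_spec_example_beta_below_one():
    spec = IdealizedAAASpec(dimension=3, neck_radius=1.25, max_sac_radius=2.0,
                            asymmetry_offset=0.96)
    want = 2.0 / (2.0 + 0.96)
    assert implied_indices(spec).beta == pytest.approx(want, rel=1e-12)
    got = compute_indices(measure_geometry(generate_mesh(spec, 0.2)))
    assert got.beta < 1.0
    assert got.beta == pytest.approx(want, rel=0.02)


def test_zero_tortuosity_centerline_is_straight():
    spec = IdealizedAAASpec(dimension=3, tortuosity_amplitude=0.0,
                            asymmetry_offset=1.0)
    m = measure_geometry(generate_mesh(spec, 0.25))
    assert m.L - m.tau < 1e-6 * m.tau


def test_target_helpers_invert_the_index_maps():
    spec = IdealizedAAASpec(dimension=3)
    off = offset_for_beta(spec, 0.45)
    assert implied_indices(replace(spec, asymmetry_offset=off)).beta == pytest.approx(0.45)
    amp = amplitude_for_epsilon(spec, 0.12)
    got = implied_indices(replace(spec, tortuosity_amplitude=amp)).epsilon
    assert got == pytest.approx(0.12, rel=1e-6)


# ---------------------------------------------------------------------------
# file round trip / renumbering invariance
# ---------------------------------------------------------------------------

def _measurement_tuple(m):
    return (m.L, m.tau, m.d_proximal_neck, m.r, m.R, m.D_AMAX, m.L_AAA)


def test_msh_round_trip_preserves_measurements(tmp_path):
    spec = IdealizedAAASpec(dimension=2, asymmetry_offset=0.8,
                            tortuosity_amplitude=1.0)
    mesh = generate_mesh(spec, 0.2)
    path = tmp_path / "case.msh"
    mesh_io.write_msh(mesh, path)
    back = mesh_io.read_msh(path)
    assert np.array_equal(back.elements, mesh.elements)
    assert np.allclose(back.points, mesh.points, rtol=0, atol=0)
    assert _measurement_tuple(measure_geometry(back)) == pytest.approx(
        _measurement_tuple(measure_geometry(mesh))
    )


def test_node_renumbering_leaves_measurements_invariant():
    spec = IdealizedAAASpec(dimension=2, asymmetry_offset=0.8)
    mesh = generate_mesh(spec, 0.25)
    rng = np.random.default_rng(7)
    perm = rng.permutation(mesh.npoints)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(mesh.npoints)
    permuted = SimplexMesh(
        points=mesh.points[perm],
        elements=inv[mesh.elements],
        facets=inv[mesh.facets],
        facet_tags=mesh.facet_tags.copy(),
        facet_elements=mesh.facet_elements.copy(),
    )
    assert _measurement_tuple(measure_geometry(permuted)) == pytest.approx(
        _measurement_tuple(measure_geometry(mesh))
    )


def test_vtu_export_writes_fields(tmp_path):
    spec = IdealizedAAASpec(dimension=2).straight()
    mesh = generate_mesh(spec, 0.3)
    path = tmp_path / "mesh.vtu"
    mesh_io.write_vtu(mesh, path, point_data={"speed": np.zeros(mesh.npoints)})
    text = path.read_text()
    assert "UnstructuredGrid" in text and 'Name="speed"' in text
    assert f'NumberOfCells="{mesh.nelements}"' in text
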