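"""WSS extraction, classification, recirculation and summaries."""

import math

import numpy as np
import pytest

from aaaflow.geometry import IdealizedAAASpec
from aaaflow.meshing import generate_mesh, measure_geometry
from aaaflow.postprocess import (
    WSSField,
    classify_wss,
    compute_wss,
    extract_cross_sections,
    normalized_pressure,
    peak_systole_snapshot,
    recirculation_fraction,
    summarize,
)
from aaaflow.solver import FlowField
from aaaflow.waveforms import Waveform


def _static_field(mesh, u=None, p=None, times=(0.0,)):
    n = mesh.npoints
    u = np.zeros((n, mesh.dim)) if u is None else u
    p = np.zeros(n) if p is None else p
    nt = len(times)
    return FlowField(
        times=np.asarray(times),
        u=np.broadcast_to(u, (nt,) + u.shape).copy(),
        p=np.broadcast_to(p, (nt,) + p.shape).copy(),
        mesh=mesh,
        diagnostics={},
    )


@pytest.fixture(scope="module")
def channel():
    spec = IdealizedAAASpec(
        dimension=2, inlet_extension=2, outlet_extension=2, sac_length=2
    ).straight()
    return generate_mesh(spec, 0.125, axial_edge_length=0.2)


def test_wss_zero_for_zero_flow(channel, props):
    wss = compute_wss(_static_field(channel), channel, props, 0.0)
    assert np.all(wss.values == 0.0)


def test_wss_plane_poiseuille(channel, channel_steady, props):
    """tau_w = 6 mu U / h for the plane channel (adjacent-element
    gradient; first-order accurate at the wall)."""
    wss = compute_wss(channel_steady, channel, props, channel_steady.times[-1])
    band = (wss.centroids[:, 0] > 0.015) & (wss.centroids[:, 0] < 0.045)
    exact = 6 * props.dynamic_viscosity * 0.1 / 0.025
    assert np.median(wss.values[band]) == pytest.approx(exact, rel=0.10)


def test_classification_two_valued_field():
    n = 10
    values = np.array([1.0] * 5 + [3.0] * 5)
    areas = np.ones(n)
    cents = np.zeros((n, 2))
    cents[:, 0] = np.linspace(0.0, 1.0, n)
    wss = WSSField(values=values, centroids=cents, areas=areas,
                   facet_ids=np.arange(n))
    out = classify_wss(wss, (0.0, 1.0))
    assert out.threshold == pytest.approx(2.0)
    assert list(out.labels[:5]) == ["low"] * 5
    assert list(out.labels[5:]) == ["high"] * 5


def test_classification_uniform_field_is_all_high():
    n = 6
    wss = WSSField(values=np.full(n, 2.0), centroids=np.zeros((n, 2)),
                   areas=np.ones(n), facet_ids=np.arange(n))
    out = classify_wss(wss, (0.0, 1.0))
    assert np.all(out.labels == "high")   # ties go to high


def test_classification_empty_sac_warns():
    n = 4
    wss = WSSField(values=np.arange(1.0, 5.0), centroids=np.zeros((n, 2)),
                   areas=np.ones(n), facet_ids=np.arange(n))
    with pytest.warns(UserWarning, match="sac"):
        classify_wss(wss, (10.0, 11.0))


def test_recirculation_zero_for_unidirectional_flow(channel, channel_steady):
    frac, zones = recirculation_fraction(
        channel_steady, channel, (0.02, 0.04), channel_steady.times[-1]
    )
    assert frac == 0.0 and zones == 0


def test_recirculation_matches_reversed_patch_measure(channel):
    """Negating the flow in a marked subregion yields exactly that
    subregion's measure fraction (to one element layer)."""
    n = channel.npoints
    u = np.zeros((n, 2))
    u[:, 0] = 1.0
    sac = (0.015, 0.045)
    patch = (0.02, 0.029)  # ~30% of the sac interval
    pts = channel.points
    inside = (pts[:, 0] >= patch[0]) & (pts[:, 0] <= patch[1])
    u[inside, 0] = -1.0
    field = _static_field(channel, u=u)
    frac, zones = recirculation_fraction(field, channel, sac, 0.0)
    expect = (patch[1] - patch[0]) / (sac[1] - sac[0])
    assert frac == pytest.approx(expect, abs=0.035)
    assert zones == 1


def test_normalized_pressure_ramp_and_constant(channel):
    pts = channel.points
    ramp = 1000.0 * (pts[:, 0].max() - pts[:, 0]) / (pts[:, 0].max() - pts[:, 0].min())
    f = _static_field(channel, p=ramp)
    np_wall = normalized_pressure(f, 0.0)
    wall_nodes = channel.facet_nodes("wall")
    zw = pts[wall_nodes, 0]
    assert np_wall[np.argmin(zw)] == pytest.approx(1.0)
    assert np_wall[np.argmax(zw)] == pytest.approx(0.0)
    const = _static_field(channel, p=np.full(channel.npoints, 55.5))
    assert np.all(normalized_pressure(const, 0.0) == 0.0)


def test_poiseuille_wall_pressure_decreases_downstream(channel, channel_steady):
    npw = normalized_pressure(channel_steady, channel_steady.times[-1])
    wall_nodes = channel.facet_nodes("wall")
    z = channel.points[wall_nodes, 0]
    order = np.argsort(z)
    # monotone decrease up to solver noise
    diffs = np.diff(npw[order])
    assert np.median(diffs) <= 0
    assert npw[order][0] > 0.9 and npw[order][-1] < 0.1


def _times_field(times):
    class _T:
        pass
    mesh = generate_mesh(IdealizedAAASpec(
        dimension=2, inlet_extension=1, outlet_extension=1, sac_length=1
    ).straight(), 0.5)
    return _static_field(mesh, times=times)


@pytest.mark.parametrize("T,peak,times,expect", [
    (1.0, 0.2, np.arange(0, 2.01, 0.01), 1.2),
    (0.8, 0.16, np.arange(0, 1.61, 0.01), 0.96),
])
def test_peak_systole_snapshot(T, peak, times, expect):
    f = _times_field(times)
    w = Waveform(period=T, peak_time=peak, coeffs=(1.0,))
    assert peak_systole_snapshot(f, w) == pytest.approx(expect, abs=1e-9)


def test_peak_systole_requires_two_cycles():
    f = _times_field(np.arange(0, 1.01, 0.01))
    w = Waveform(period=1.0, peak_time=0.2, coeffs=(1.0,))
    with pytest.raises(ValueError, match="two"):
        peak_systole_snapshot(f, w)


def test_cross_sections_on_3d_sac(props):
    spec = IdealizedAAASpec(dimension=3)
    mesh = generate_mesh(spec, 0.25)
    meas, details = measure_geometry(mesh, return_details=True)
    n = mesh.npoints
    u = np.zeros((n, 3))
    u[:, 0] = 1.0
    field = _static_field(mesh, u=u)
    secs = extract_cross_sections(field, mesh, details, 0.0)
    assert [s.label for s in secs] == ["proximal neck", "midsection", "distal neck"]
    d_neck = meas.d_proximal_neck * 0.01
    # neck sections open just past the 1.05x threshold
    a_neck = math.pi * (1.05 * d_neck / 2) ** 2
    assert secs[0].area == pytest.approx(a_neck, rel=0.02)
    # uniform axial flow: flux centroid coincides with the area centroid
    assert secs[1].flux_centroid_offset < 0.02 * meas.D_AMAX * 0.01


def test_summary_of_zero_flow_field(channel, props):
    f = _static_field(channel, times=(0.0, 1.2, 2.0))
    w = Waveform(period=1.0, peak_time=0.2, coeffs=(1.0,))
    s = summarize(f, channel, None, props, w)
    assert s.sac_mean_wss == 0.0
    assert s.recirculation_fraction == 0.0
    assert s.reynolds_inlet == 0.0
    assert s.pressure_drop == 0.0


def test_summary_of_sac_run_is_consistent(sac_run, props):
    s = summarize(sac_run["field"], sac_run["mesh"], sac_run["details"],
                  props, sac_run["inlet_waveform"])
    assert s.snapshot_time == pytest.approx(1.2, abs=0.05)
    assert s.sac_max_wss >= s.sac_mean_wss >= 0
    assert 0.0 <= s.recirculation_fraction <= 1.0
    assert np.isfinite(s.neck_max_wss)
    assert 0.0 <= s.low_wss_recirc_jaccard <= 1.0
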