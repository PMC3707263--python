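"""Waveform templates, inflow calibration and the parabolic inlet profile."""

import math

import numpy as np
import pytest

from aaaflow.geometry import IdealizedAAASpec
from aaaflow.meshing import generate_mesh
from aaaflow.waveforms import (
    MMHG,
    InletGeometry,
    Waveform,
    calibrate_inflow,
    parabolic_inlet,
    reynolds_number,
    template_waveforms,
)


@pytest.fixture(scope="module")
def templates():
    return template_waveforms(T=1.0, peak_time=0.2)


def test_waveforms_are_periodic(templates):
    t = np.linspace(0.0, 1.0, 257)
    for w in templates:
        assert np.allclose(w(t), w(t + w.period), rtol=0, atol=1e-12 * abs(w(0.2)))


def test_inlet_peaks_exactly_at_peak_time(templates):
    w_in, _ = templates
    t = np.linspace(0.0, 1.0, 100001)
    assert w_in(0.2) >= w_in(t).max() - 1e-12
    assert w_in(0.2) == pytest.approx(1.0)  # unit amplitude before calibration


def test_inlet_has_mild_diastolic_flow(templates):
    w_in, _ = templates
    t = np.linspace(0.0, 1.0, 2001)
    assert w_in.mean > 0.1                   # net forward flow
    assert w_in(t).min() > -0.05             # at most a brief weak reversal


def test_outlet_pressure_mean_and_range(templates):
    _, w_out = templates
    t = np.linspace(0.0, 1.0, 4001)
    mean = np.trapezoid(w_out(t), t) / 1.0
    assert mean == pytest.approx(100.0 * MMHG, rel=0.05)
    assert w_out(t).max() == pytest.approx(120.0 * MMHG, rel=1e-6)
    assert w_out(t).min() == pytest.approx(80.0 * MMHG, rel=1e-6)


def test_calibration_constant_waveform_closed_form():
    w = Waveform(period=0.8, peak_time=0.4, coeffs=(2.0,))
    area = 3e-4
    cal = calibrate_inflow(w, area, cycle_volume=500e-6)
    # scale = V / (u * A * T)
    assert cal.calibration_scale == pytest.approx(500e-6 / (2.0 * area * 0.8))
    assert cal.cycle_integral() * area == pytest.approx(500e-6)


def test_calibrated_template_reintegrates_to_cycle_volume(templates):
    w_in, _ = templates
    area = math.pi * 0.0125**2
    cal = calibrate_inflow(w_in, area, 500e-6)
    t = np.linspace(0.0, 1.0, 20001)
    vol = np.trapezoid(cal(t) * area, t)
    assert vol == pytest.approx(500e-6, rel=1e-3)


def test_doubling_area_halves_amplitude(templates):
    w_in, _ = templates
    a = calibrate_inflow(w_in, 1e-4, 500e-6)
    b = calibrate_inflow(w_in, 2e-4, 500e-6)
    assert b.amplitude == pytest.approx(a.amplitude / 2.0)


def test_calibration_rejects_zero_integral():
    w = Waveform(period=1.0, peak_time=0.2, coeffs=(0.0, 1.0))
    with pytest.raises(ValueError, match="calibrat"):
        calibrate_inflow(w, 1e-4)


@pytest.fixture(scope="module")
def tube_inlet():
    spec = IdealizedAAASpec(
        dimension=3, inlet_extension=1.0, outlet_extension=1.0, sac_length=1.0
    ).straight()
    mesh = generate_mesh(spec, 0.1, axial_edge_length=0.3)
    return mesh, InletGeometry.from_mesh(mesh)


def test_parabolic_profile_center_rim_and_mean(templates, tube_inlet):
    w_in, _ = templates
    _, geom = tube_inlet
    u_t = float(w_in(0.2))
    center = parabolic_inlet(geom.center, 0.2, w_in, geom)
    assert center[0] @ geom.axis == pytest.approx(2.0 * u_t, rel=1e-9)
    rim_pt = geom.center + np.array([0.0, geom.size / 2.0, 0.0])
    rim = parabolic_inlet(rim_pt, 0.2, w_in, geom)
    assert np.linalg.norm(rim) == pytest.approx(0.0, abs=1e-12)
    # area average over the disc equals u(t) (polar quadrature)
    nr, nth = 400, 64
    r = (np.arange(nr) + 0.5) / nr * geom.size / 2.0
    th = np.linspace(0, 2 * np.pi, nth, endpoint=False)
    rr, tt = np.meshgrid(r, th)
    pts = (geom.center[None, :]
           + rr.ravel()[:, None] * np.stack([np.zeros(rr.size),
                                             np.cos(tt.ravel()),
                                             np.sin(tt.ravel())], axis=1))
    u = parabolic_inlet(pts, 0.2, w_in, geom) @ geom.axis
    mean = np.sum(u * rr.ravel()) / np.sum(rr.ravel())
    assert mean == pytest.approx(u_t, rel=1e-3)


def test_parabolic_profile_rejects_off_plane_points(templates, tube_inlet):
    w_in, _ = templates
    _, geom = tube_inlet
    bad = geom.center + 0.01 * geom.axis
    with pytest.raises(ValueError, match="inlet plane"):
        parabolic_inlet(bad, 0.0, w_in, geom)


def test_mesh_inlet_geometry_matches_analytic_disc(tube_inlet):
    _, geom = tube_inlet
    a = 0.0125
    assert geom.area == pytest.approx(math.pi * a**2, rel=0.01)
    assert geom.perimeter == pytest.approx(2 * math.pi * a, rel=0.01)
    # hydraulic diameter of a circle is its geometric diameter
    D = 4 * geom.area / geom.perimeter
    assert D == pytest.approx(2 * a, rel=0.02)


def test_reynolds_number_definition():
    # circle of radius a: D = 4*pi*a^2/(2*pi*a) = 2a
    a, U, nu = 0.0125, 0.2, 3.81e-6
    re = reynolds_number(U, math.pi * a**2, 2 * math.pi * a, nu)
    assert re == pytest.approx(U * 2 * a / nu, rel=1e-12)
    assert reynolds_number(0.0, 1.0, 1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        reynolds_number(1.0, 1.0, 0.0, 1.0)
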