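"""Shape indices, classification and rupture-risk flags."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from importlib.resources import files

from aaaflow.morphometry import (
    GeometricIndices,
    InvalidMeasurementError,
    RiskThresholds,
    VesselMeasurements,
    classify_shape,
    compute_indices,
    measurements_from_row,
    read_measurements,
    risk_flags,
)

FIXTURE = str(files("aaaflow").joinpath("data/table1.csv"))

# printed index values (case, chi, beta, gamma, epsilon); beta of cases 2
# and 3 is internally inconsistent with the printed radii (r/R gives
# 0.385 / 0.502) and is checked with a wide band instead
PRINTED = [
    (1, 1.408, 0.608, 0.588, 0.123),
    (2, 1.421, 0.388, 0.589, 0.029),
    (3, 1.176, 0.508, 0.340, 0.223),
    (4, 1.550, 0.309, 0.258, 0.150),
    (5, 1.000, 1.000, None, 0.047),
]
BETA_INCONSISTENT = {2, 3}


def _case(case_no):
    df = read_measurements(FIXTURE)
    row = df[df["case"] == str(case_no)].iloc[0]
    return measurements_from_row(row)


@pytest.mark.parametrize("case_no,chi,beta,gamma,epsilon", PRINTED)
def test_printed_indices_reproduced(case_no, chi, beta, gamma, epsilon):
    idx = compute_indices(_case(case_no))
    assert idx.chi == pytest.approx(chi, abs=2e-3)
    assert idx.epsilon == pytest.approx(epsilon, abs=2e-3)
    if gamma is None:
        assert idx.gamma is None
    else:
        assert idx.gamma == pytest.approx(gamma, abs=2e-3)
    if case_no in BETA_INCONSISTENT:
        assert idx.beta == pytest.approx(beta, abs=7e-3)
    else:
        assert idx.beta == pytest.approx(beta, abs=2e-3)


def test_control_vessel_has_unit_indices_and_no_gamma():
    idx = compute_indices(_case(5))
    assert idx.beta == 1.0
    assert idx.chi == 1.0
    assert idx.gamma is None


def test_straight_centerline_gives_zero_epsilon():
    m = VesselMeasurements(L=30.0, tau=30.0, d_proximal_neck=2.5,
                           r=1.25, R=1.25, D_AMAX=2.5)
    assert compute_indices(m).epsilon == 0.0


@given(k=st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=50)
def test_indices_are_scale_invariant(k):
    m = _case(1)
    a = compute_indices(m)
    b = compute_indices(m.scaled(k))
    assert b.beta == pytest.approx(a.beta, rel=1e-12)
    assert b.gamma == pytest.approx(a.gamma, rel=1e-12)
    assert b.chi == pytest.approx(a.chi, rel=1e-12)
    assert b.epsilon == pytest.approx(a.epsilon, abs=1e-12)


@given(r=st.floats(min_value=0.1, max_value=2.44),
       dr=st.floats(min_value=1e-3, max_value=0.5))
@settings(deadline=None, max_examples=50)
def test_beta_strictly_increasing_in_posterior_radius(r, dr):
    base = dict(L=300.0, tau=290.0, d_proximal_neck=2.8, R=2.45,
                D_AMAX=3.9, L_AAA=6.7)
    lo = compute_indices(VesselMeasurements(r=r, **base)).beta
    hi = compute_indices(VesselMeasurements(r=min(r + dr, 2.449), **base)).beta
    assert hi > lo


@given(extra=st.floats(min_value=1e-6, max_value=100.0))
@settings(deadline=None, max_examples=50)
def test_epsilon_strictly_increasing_in_centerline_length(extra):
    base = dict(tau=290.0, d_proximal_neck=2.8, r=1.0, R=2.0, D_AMAX=3.9)
    lo = compute_indices(VesselMeasurements(L=290.0, **base)).epsilon
    hi = compute_indices(VesselMeasurements(L=290.0 + extra, **base)).epsilon
    assert hi > lo


def test_swapped_radii_are_exchanged_with_warning():
    with pytest.warns(UserWarning, match="swapped"):
        m = VesselMeasurements(L=300.0, tau=290.0, d_proximal_neck=2.8,
                               r=2.45, R=1.49, D_AMAX=3.9, L_AAA=6.7)
    assert m.r == 1.49 and m.R == 2.45
    assert compute_indices(m).beta <= 1.0


@pytest.mark.parametrize("field,kwargs", [
    ("d_proximal_neck", dict(L=300, tau=290, d_proximal_neck=0.0, r=1, R=2, D_AMAX=3.9)),
    ("tau", dict(L=300, tau=-1.0, d_proximal_neck=2.8, r=1, R=2, D_AMAX=3.9)),
    ("L_AAA", dict(L=300, tau=290, d_proximal_neck=2.8, r=1, R=2, D_AMAX=3.9, L_AAA=0.0)),
    ("L", dict(L=200, tau=290, d_proximal_neck=2.8, r=1, R=2, D_AMAX=3.9)),
])
def test_invalid_measurements_name_the_offending_field(field, kwargs):
    with pytest.raises(InvalidMeasurementError) as err:
        compute_indices(VesselMeasurements(**kwargs))
    assert err.value.field_name == field


@pytest.mark.parametrize("gamma,label", [
    (0.9, "saccular"),
    (0.258, "fusiform"),
    (0.5, "saccular"),      # boundary belongs to saccular
    (None, "not-applicable"),
])
def test_shape_classification(gamma, label):
    idx = GeometricIndices(beta=0.5, chi=1.4, epsilon=0.1, gamma=gamma)
    assert classify_shape(idx) == label


def test_risk_flags_case4_asymmetry():
    m = _case(4)
    flags = risk_flags(m, compute_indices(m))
    assert flags.flag_asymmetry
    assert flags.flag_saccular          # gamma 0.258 < 0.6
    assert not flags.flag_diameter      # 4.031 cm < 5.5 cm
    assert not flags.flag_deformation   # 1.55 < 3.3


def test_risk_flags_control_all_false():
    m = _case(5)
    flags = risk_flags(m, compute_indices(m))
    assert not flags.any_flag


def test_risk_flags_single_threshold_crossing():
    m = VesselMeasurements(L=300, tau=299, d_proximal_neck=1.0, r=1.0, R=1.0,
                           D_AMAX=3.4, L_AAA=5.0)
    idx = compute_indices(m)
    assert idx.chi == pytest.approx(3.4)
    flags = risk_flags(m, idx)
    assert flags.flag_deformation
    assert not (flags.flag_diameter or flags.flag_asymmetry)
    assert flags.thresholds == RiskThresholds()
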