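"""Parameterized idealized AAA lumen geometries.

A single-lumen abdominal aorta is described by a straight entrance and exit
tube of ``neck_radius`` joined by an optional fusiform-to-saccular bulge.
The bulge is a cosine-squared radial bump (C1, compactly supported over
``sac_length``), so the sac extent is exact and the saccular index is
controllable in closed form.  Anterior/posterior asymmetry is produced by an
anterior-only extra dilation ``asymmetry_offset * bump`` (only the anterior
wall is dilated; the posterior wall keeps the symmetric profile), and
centerline tortuosity by a transverse sinusoid of amplitude
``tortuosity_amplitude``, phase-locked so its slope vanishes at the sac
center.  All spec lengths are centimetres.

Axes convention: axis 0 is axial ("z" of the vessel), axis 1 is the
anterior(+)/posterior(-) direction; in 3D axis 2 is lateral and carries the
tortuosity offset (in 2D the single transverse axis carries both asymmetry
and tortuosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .morphometry import VesselMeasurements, compute_indices, GeometricIndices

__all__ = [
    "IdealizedAAASpec",
    "bump",
    "radius_profile",
    "centerline_offset",
    "section_radius",
    "analytic_measurements",
    "implied_indices",
    "amplitude_for_epsilon",
    "offset_for_beta",
]

#: diameters above ``SAC_THRESHOLD * neck diameter`` delimit the sac
SAC_THRESHOLD = 1.05


@dataclass(frozen=True)
class IdealizedAAASpec:
    """Parameters of an idealized AAA lumen (all lengths in cm)."""

    neck_radius: float = 1.25
    max_sac_radius: float = 1.9
    sac_length: float = 7.0
    sac_center: Optional[float] = None
    asymmetry_offset: float = 0.0
    tortuosity_amplitude: float = 0.0
    tortuosity_wavelength: Optional[float] = None
    inlet_extension: float = 6.0
    outlet_extension: float = 6.0
    dimension: int = 2

    def __post_init__(self):
        for name in ("neck_radius", "max_sac_radius", "sac_length",
                     "inlet_extension", "outlet_extension"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.max_sac_radius < self.neck_radius:
            raise ValueError("max_sac_radius must be >= neck_radius")
        if self.asymmetry_offset < 0 or not math.isfinite(self.asymmetry_offset):
            raise ValueError("asymmetry_offset must be finite and >= 0")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.sac_center is not None:
            if not (0.0 < self.sac_center < self.total_length):
                raise ValueError("sac_center must lie inside the vessel")

    @property
    def total_length(self) -> float:
        return self.inlet_extension + self.sac_length + self.outlet_extension

    @property
    def sac_center_(self) -> float:
        """Sac center with its default (middle of the sac segment) applied."""
        if self.sac_center is not None:
            return self.sac_center
        return self.inlet_extension + 0.5 * self.sac_length

    @property
    def wavelength_(self) -> float:
        """Tortuosity wavelength default: one period over the vessel length."""
        if self.tortuosity_wavelength is not None:
            return self.tortuosity_wavelength
        return self.total_length

    def straight(self) -> "IdealizedAAASpec":
        """The matching straight-tube control (no sac, no tortuosity)."""
        return replace(
            self,
            max_sac_radius=self.neck_radius,
            asymmetry_offset=0.0,
            tortuosity_amplitude=0.0,
        )


def _check_domain(spec: IdealizedAAASpec, z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > spec.total_length + 1e-12):
        raise ValueError(
            f"axial coordinate outside [0, {spec.total_length}] cm"
        )
    return z


def bump(spec: IdealizedAAASpec, z) -> np.ndarray:
    """Cosine-squared bump: 1 at the sac center, 0 outside the sac support."""
    z = np.asarray(z, dtype=float)
    xi = (z - spec.sac_center_) / spec.sac_length
    out = np.where(np.abs(xi) < 0.5, np.cos(np.pi * xi) ** 2, 0.0)
    return out


def radius_profile(spec: IdealizedAAASpec, z):
    """Posterior and anterior wall offsets from the reference axis at ``z``.

    Returns ``(posterior, anterior)`` in cm.  The symmetric profile rises
    from ``neck_radius`` to ``max_sac_radius``; the anterior offset gains an
    extra ``asymmetry_offset * bump`` (anterior-only dilation).
    """
    z = _check_domain(spec, z)
    b = bump(spec, z)
    symmetric = spec.neck_radius + (spec.max_sac_radius - spec.neck_radius) * b
    anterior = symmetric + spec.asymmetry_offset * b
    return symmetric, anterior


def centerline_offset(spec: IdealizedAAASpec, z, derivative: bool = False):
    """Transverse sinusoidal centerline offset (or its slope) at ``z``.

    The phase puts a slope extremum of zero at the sac center so that the
    midsection cross-section stays normal to the axial direction.
    """
    z = np.asarray(z, dtype=float)
    w = 2.0 * np.pi / spec.wavelength_
    phase = w * (z - spec.sac_center_)
    if derivative:
        return -spec.tortuosity_amplitude * w * np.sin(phase)
    return spec.tortuosity_amplitude * np.cos(phase)


def section_radius(spec: IdealizedAAASpec, z, theta):
    """Radial boundary distance of the 3D cross-section at angle ``theta``.

    ``theta`` is measured in the transverse plane from the lateral axis
    toward anterior (+pi/2 = anterior, -pi/2 = posterior).  The posterior
    half is a semicircle of the symmetric radius; the anterior half is a
    half-ellipse stretched to the dilated anterior offset, giving a C1
    egg-shaped section that degenerates to a circle when the asymmetry
    offset vanishes.
    """
    theta = np.asarray(theta, dtype=float)
    post, ant = radius_profile(spec, z)
    post = np.broadcast_to(np.asarray(post, float), theta.shape).astype(float)
    ant = np.broadcast_to(np.asarray(ant, float), theta.shape).astype(float)
    s = np.sin(theta)
    c = np.cos(theta)
    rho = np.where(
        s <= 0.0,
        post,
        post * ant / np.sqrt(ant**2 * c**2 + post**2 * s**2),
    )
    return rho


def _diameter_profile(spec: IdealizedAAASpec, z):
    """Maximum cross-section extent at ``z`` (the anterior-posterior one)."""
    post, ant = radius_profile(spec, z)
    return post + ant


def _axis_path(spec: IdealizedAAASpec, n: int = 4001):
    z = np.linspace(0.0, spec.total_length, n)
    c = centerline_offset(spec, z)
    return z, c


def _arc_length(z: np.ndarray, c: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(z), np.diff(c))))


def analytic_measurements(spec: IdealizedAAASpec, n_axial: int = 4001) -> VesselMeasurements:
    """Measure the continuum geometry with the package's mesh conventions.

    The sac is the axial interval where the diameter exceeds
    ``SAC_THRESHOLD`` times the neck diameter (closed form for the
    cosine-squared bump); radii r/R are taken from the healthy reference
    axis at the midsection; L is the arc length of the reference axis and
    tau the endpoint chord.
    """
    a0 = spec.neck_radius
    d0 = 2.0 * a0
    peak_extra = 2.0 * (spec.max_sac_radius - a0) + spec.asymmetry_offset

    z, c = _axis_path(spec, n_axial)
    L = _arc_length(z, c)
    tau = float(np.hypot(z[-1] - z[0], c[-1] - c[0]))
    L = max(L, tau)

    threshold_extra = (SAC_THRESHOLD - 1.0) * d0
    if peak_extra > threshold_extra:
        frac = threshold_extra / peak_extra  # bump value at the sac boundary
        half_width = spec.sac_length * math.acos(math.sqrt(frac)) / math.pi
        L_AAA = 2.0 * half_width
        D_AMAX = d0 + peak_extra
        r = spec.max_sac_radius
        R = spec.max_sac_radius + spec.asymmetry_offset
    else:
        L_AAA = None
        D_AMAX = d0
        r = R = a0
    return VesselMeasurements(
        L=L,
        tau=tau,
        d_proximal_neck=d0,
        r=r,
        R=R,
        D_AMAX=D_AMAX,
        L_AAA=L_AAA,
    )


def implied_indices(spec: IdealizedAAASpec) -> GeometricIndices:
    """Shape indices implied by the continuum spec (the round-trip targets)."""
    return compute_indices(analytic_measurements(spec))


def offset_for_beta(spec: IdealizedAAASpec, beta: float) -> float:
    """Asymmetry offset producing a target asymmetry index ``beta``."""
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    return spec.max_sac_radius * (1.0 / beta - 1.0)


def amplitude_for_epsilon(spec: IdealizedAAASpec, epsilon: float) -> float:
    """Tortuosity amplitude producing a target tortuosity index ``epsilon``."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return 0.0

    def eps_of(amplitude: float) -> float:
        s = replace(spec, tortuosity_amplitude=amplitude)
        return implied_indices(s).epsilon - epsilon

    hi = spec.wavelength_
    while eps_of(hi) < 0:
        hi *= 2.0
    return float(brentq(eps_of, 0.0, hi, xtol=1e-10))
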