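"""Pulsatile boundary waveforms and the parabolic inlet profile.

The exact in-vivo waveform ordinates used in patient studies are not
tabulated in the literature we follow, so the package ships an analytic
template family clearly labelled as a stand-in: a truncated von-Mises
cosine series for the inlet mean velocity (one dominant systolic peak per
cycle, mild diastolic flow) and a sinusoidal outlet pressure oscillating
between diastolic 80 and systolic 120 mmHg, both peaking at ``peak_time``.

The inlet template has unit peak amplitude; :func:`calibrate_inflow`
rescales it so one cardiac cycle carries a prescribed volume (default
500 mL) through a given inlet area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import iv

__all__ = [
    "Waveform",
    "template_waveforms",
    "calibrate_inflow",
    "parabolic_inlet",
    "InletGeometry",
    "reynolds_number",
    "MMHG",
]

MMHG = 133.322  # Pa per mmHg


@dataclass(frozen=True)
class Waveform:
    """Periodic scalar waveform as a low-order cosine series.

    value(t) = amplitude * sum_n coeffs[n] * cos(n * 2*pi*(t - peak_time)/period)

    With nonnegative coefficients the maximum falls exactly at
    ``peak_time`` (mod period).
    """

    period: float
    peak_time: float
    coeffs: Tuple[float, ...]
    amplitude: float = 1.0
    name: str = ""
    calibration_scale: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.peak_time < self.period):
            raise ValueError("peak_time must lie strictly inside one period")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        phase = 2.0 * np.pi * (t - self.peak_time) / self.period
        out = np.zeros_like(t)
        for n, a in enumerate(self.coeffs):
            out = out + a * np.cos(n * phase)
        return self.amplitude * out

    @property
    def mean(self) -> float:
        """Exact mean over one period (the n=0 coefficient)."""
        return self.amplitude * self.coeffs[0]

    def cycle_integral(self) -> float:
        return self.mean * self.period


def template_waveforms(
    T: float = 1.0,
    peak_time: float = 0.2,
    kappa: float = 4.0,
    n_harmonics: int = 4,
    diastolic_mmHg: float = 80.0,
    systolic_mmHg: float = 120.0,
) -> Tuple[Waveform, Waveform]:
    """Template (inlet velocity, outlet pressure) waveform pair.

    The inlet is the order-``n_harmonics`` Fourier truncation of a
    von-Mises pulse ``exp(kappa*cos)`` normalized to unit peak; sharper
    pulses (larger ``kappa``) raise the systolic-to-mean ratio.  The outlet
    pressure (in Pa) swings between the diastolic and systolic defaults
    with its peak aligned to ``peak_time``.
    """
    if not (0.0 < peak_time < T):
        raise ValueError("need 0 < peak_time < T")
    raw = [float(iv(0, kappa))] + [2.0 * float(iv(n, kappa)) for n in range(1, n_harmonics + 1)]
    peak = sum(raw)
    coeffs = tuple(a / peak for a in raw)
    inlet = Waveform(period=T, peak_time=peak_time, coeffs=coeffs, name="inlet-velocity")

    p_mean = 0.5 * (diastolic_mmHg + systolic_mmHg) * MMHG
    p_amp = 0.5 * (systolic_mmHg - diastolic_mmHg) * MMHG
    outlet = Waveform(
        period=T, peak_time=peak_time, coeffs=(p_mean, p_amp), name="outlet-pressure"
    )
    return inlet, outlet


def calibrate_inflow(
    w: Waveform, inlet_area: float, cycle_volume: float = 500e-6
) -> Waveform:
    """Scale ``w`` so one cycle carries ``cycle_volume`` (m^3) through
    ``inlet_area`` (m^2); the applied scale factor is recorded."""
    if inlet_area <= 0:
        raise ValueError("inlet_area must be > 0")
    integral = w.cycle_integral() * inlet_area
    if integral <= 0:
        raise ValueError("waveform cycle integral is not positive; cannot calibrate")
    scale = cycle_volume / integral
    return replace(w, amplitude=w.amplitude * scale, calibration_scale=scale)


@dataclass(frozen=True)
class InletGeometry:
    """Geometry of the inlet plane needed by the parabolic profile."""

    center: np.ndarray     # (dim,) m
    axis: np.ndarray       # unit vector, flow direction (into the domain)
    area: float            # m^2 (per metre width in 2D)
    perimeter: float       # m (2.0 in 2D: both plates, per unit width)
    size: float            # diameter (3D) or channel height (2D), m
    dim: int

    @classmethod
    def from_mesh(cls, mesh, tag: str = "inlet") -> "InletGeometry":
        mask = mesh.facet_mask(tag)
        if not np.any(mask):
            raise ValueError(f"mesh has no '{tag}' facets")
        measures = mesh.facet_measures(mask)
        area = float(measures.sum())
        centers = mesh.points[mesh.facets[mask]].mean(axis=1)
        center = (centers * measures[:, None]).sum(axis=0) / area
        normal = mesh.facet_normals(mask).mean(axis=0)
        normal /= np.linalg.norm(normal)
        axis = -normal  # boundary normals point outward; flow goes inward
        if mesh.dim == 2:
            perimeter = 2.0
            size = area
        else:
            # free edges of the inlet patch form its rim
            edges = []
            for f in mesh.facets[mask]:
                edges += [tuple(sorted((f[0], f[1]))),
                          tuple(sorted((f[1], f[2]))),
                          tuple(sorted((f[0], f[2])))]
            uniq, counts = np.unique(np.array(edges), axis=0, return_counts=True)
            rim = uniq[counts == 1]
            perimeter = float(
                np.linalg.norm(mesh.points[rim[:, 0]] - mesh.points[rim[:, 1]], axis=1).sum()
            )
            size = 2.0 * math.sqrt(area / math.pi)
        return cls(center=center, axis=axis, area=area,
                   perimeter=perimeter, size=size, dim=mesh.dim)


def parabolic_inlet(
    points: np.ndarray,
    t: float,
    w: Waveform,
    inlet: InletGeometry,
    plane_tol: float = 1e-6,
) -> np.ndarray:
    """Fully developed parabolic inlet velocity vectors at ``points``.

    3D (circular section): axial speed ``2*u(t)*(1 - (2*rho/d)**2)`` with
    ``rho`` the distance from the inlet centroid and ``d`` the diameter;
    transverse components are zero and the profile vanishes at the rim.
    2D (plane channel) uses ``(3/2)*u(t)*(1 - (2*y/h)**2)`` so that the
    cross-section mean is again exactly ``u(t)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = points - inlet.center
    off_plane = rel @ inlet.axis
    scale = max(inlet.size, 1e-300)
    if np.any(np.abs(off_plane) > plane_tol * scale):
        raise ValueError("point does not lie on the inlet plane")
    rel_in = rel - off_plane[:, None] * inlet.axis
    rho = np.linalg.norm(rel_in, axis=1)
    u_mean = float(w(t))
    xi = np.clip(2.0 * rho / inlet.size, 0.0, 1.0)
    factor = 2.0 if inlet.dim == 3 else 1.5
    speed = factor * u_mean * (1.0 - xi**2)
    return speed[:, None] * inlet.axis


def reynolds_number(U: float, area: float, perimeter: float, nu: float) -> float:
    """Re = U*D/nu with the hydraulic diameter D = 4*area/perimeter."""
    if perimeter <= 0 or area <= 0 or nu <= 0:
        raise ValueError("area, perimeter and nu must be > 0")
    D = 4.0 * area / perimeter
    return U * D / nu
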