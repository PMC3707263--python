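"""Geometric morphometry of abdominal aortic aneurysms.

Four dimensionless indices summarize the shape of an AAA measured on its
lumen (all raw measurements in centimetres):

* asymmetry index        ``beta = r / R``        (posterior / anterior midsection radius)
* saccular index         ``gamma = D_AMAX / L_AAA``
* deformation ratio      ``chi = D_AMAX / d_proximal_neck``
* tortuosity index       ``epsilon = L / tau - 1``

``beta = 1`` means an azimuthally symmetric sac, ``chi = 1`` a
non-aneurysmal aorta, ``epsilon = 0`` a straight vessel.  A saccular
(near-spherical) aneurysm has ``gamma`` close to 1, a fusiform (elongated)
one close to 0.  Literature rupture-risk cutoffs evaluated here:
``D_AMAX > 5.5 cm``, ``beta < 0.4``, ``chi > 3.3`` and ``gamma < 0.6``.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "VesselMeasurements",
    "GeometricIndices",
    "RiskAssessment",
    "RiskThresholds",
    "InvalidMeasurementError",
    "compute_indices",
    "classify_shape",
    "risk_flags",
    "read_measurements",
]


class InvalidMeasurementError(ValueError):
    """A vessel measurement is missing, non-positive or inconsistent."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _require_positive(name: str, value: Optional[float], optional: bool = False):
    if value is None:
        if optional:
            return
        raise InvalidMeasurementError(name, "measurement is required")
    if not math.isfinite(value) or value <= 0.0:
        raise InvalidMeasurementError(name, f"must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class VesselMeasurements:
    """Raw lengths and diameters of one vessel, in centimetres.

    ``L`` is the centerline length of the tortuous vessel and ``tau`` the
    straight-line (hypothetical healthy) length between its endpoints.
    ``r`` / ``R`` are the midsection radii from the reference axis to the
    posterior / anterior wall.  ``L_AAA`` (sac length) and
    ``d_distal_neck`` are absent for a non-aneurysmal control vessel.
    """

    L: float
    tau: float
    d_proximal_neck: float
    r: float
    R: float
    D_AMAX: float
    L_AAA: Optional[float] = None
    d_distal_neck: Optional[float] = None

    def __post_init__(self):
        _require_positive("L", self.L)
        _require_positive("tau", self.tau)
        _require_positive("d_proximal_neck", self.d_proximal_neck)
        _require_positive("r", self.r)
        _require_positive("R", self.R)
        _require_positive("D_AMAX", self.D_AMAX)
        _require_positive("L_AAA", self.L_AAA, optional=True)
        _require_positive("d_distal_neck", self.d_distal_neck, optional=True)
        # A centerline is never shorter than its endpoints' chord; allow a
        # hair of numerical slack for measured geometries.
        if self.L < self.tau * (1.0 - 1e-9):
            raise InvalidMeasurementError(
                "L", f"centerline length {self.L} is shorter than chord tau={self.tau}"
            )
        if self.r > self.R:
            # Posterior/anterior convention: r <= R.  Synthetic geometries may
            # invert the labels; swap rather than emit beta > 1.
            warnings.warn(
                "r > R: posterior/anterior radii look swapped; exchanging them",
                stacklevel=2,
            )
            r_old, R_old = self.r, self.R
            object.__setattr__(self, "r", R_old)
            object.__setattr__(self, "R", r_old)

    def scaled(self, k: float) -> "VesselMeasurements":
        """All lengths multiplied by ``k > 0`` (indices are scale invariant)."""
        if k <= 0:
            raise ValueError("scale factor must be > 0")
        return VesselMeasurements(
            L=self.L * k,
            tau=self.tau * k,
            d_proximal_neck=self.d_proximal_neck * k,
            r=self.r * k,
            R=self.R * k,
            D_AMAX=self.D_AMAX * k,
            L_AAA=None if self.L_AAA is None else self.L_AAA * k,
            d_distal_neck=None if self.d_distal_neck is None else self.d_distal_neck * k,
        )


@dataclass(frozen=True)
class GeometricIndices:
    """The four dimensionless AAA shape indices.

    ``gamma`` is ``None`` when the vessel has no identifiable sac.
    """

    beta: float
    chi: float
    epsilon: float
    gamma: Optional[float] = None


@dataclass(frozen=True)
class RiskThresholds:
    """Literature cutoffs for the rupture-risk flags."""

    diameter_cm: float = 5.5
    beta: float = 0.4
    chi: float = 3.3
    gamma: float = 0.6


@dataclass(frozen=True)
class RiskAssessment:
    flag_diameter: bool
    flag_asymmetry: bool
    flag_deformation: bool
    flag_saccular: bool
    thresholds: RiskThresholds = field(default_factory=RiskThresholds)

    @property
    def any_flag(self) -> bool:
        return (
            self.flag_diameter
            or self.flag_asymmetry
            or self.flag_deformation
            or self.flag_saccular
        )


def compute_indices(m: VesselMeasurements) -> GeometricIndices:
    """Compute beta, gamma, chi and epsilon from raw measurements.

    ``gamma`` is left absent for a control vessel (no ``L_AAA``).

    Raises
    ------
    InvalidMeasurementError
        If a denominator is zero/negative (already rejected at construction,
        re-checked here so externally built objects fail loudly too).
    """
    for name in ("R", "d_proximal_neck", "tau"):
        _require_positive(name, getattr(m, name))
    beta = m.r / m.R
    chi = m.D_AMAX / m.d_proximal_neck
    epsilon = m.L / m.tau - 1.0
    gamma = None
    if m.L_AAA is not None:
        _require_positive("L_AAA", m.L_AAA)
        gamma = m.D_AMAX / m.L_AAA
    for name, value in (("beta", beta), ("chi", chi), ("epsilon", epsilon)):
        if not math.isfinite(value):
            raise InvalidMeasurementError(name, "index is not finite")
    return GeometricIndices(beta=beta, chi=chi, epsilon=epsilon, gamma=gamma)


SHAPE_SACCULAR = "saccular"
SHAPE_FUSIFORM = "fusiform"
SHAPE_NOT_APPLICABLE = "not-applicable"

#: gamma at or above this cut -> saccular (midpoint cut; boundary is saccular)
SACCULAR_CUT = 0.5


def classify_shape(idx: GeometricIndices) -> str:
    """Label the sac ``"saccular"`` (gamma nearer 1) or ``"fusiform"`` (nearer 0).

    The cut sits at gamma = 0.5 with the boundary assigned to saccular.
    Returns ``"not-applicable"`` when the vessel has no sac.
    """
    if idx.gamma is None:
        return SHAPE_NOT_APPLICABLE
    return SHAPE_SACCULAR if idx.gamma >= SACCULAR_CUT else SHAPE_FUSIFORM


def risk_flags(
    m: VesselMeasurements,
    idx: GeometricIndices,
    thresholds: RiskThresholds = RiskThresholds(),
) -> RiskAssessment:
    """Evaluate the four literature rupture-risk criteria.

    The saccular flag is ``False`` when gamma is absent (control vessel).
    """
    return RiskAssessment(
        flag_diameter=m.D_AMAX > thresholds.diameter_cm,
        flag_asymmetry=idx.beta < thresholds.beta,
        flag_deformation=idx.chi > thresholds.chi,
        flag_saccular=(idx.gamma is not None and idx.gamma < thresholds.gamma),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Measurement-table ingest (delimited text, decimal commas tolerated)
# ---------------------------------------------------------------------------

_FIELDS = ("L", "tau", "d_proximal_neck", "r", "R", "D_AMAX", "L_AAA", "d_distal_neck")
_REQUIRED = ("L", "tau", "d_proximal_neck", "r", "R", "D_AMAX")


def _to_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    if cell in ("", "-", "—", "NA", "nan", "None"):
        return None
    return float(cell.replace(",", "."))


def read_measurements(path) -> pd.DataFrame:
    """Read a delimited measurement table into a DataFrame (one row per case).

    Accepts ``;``/tab/``,`` delimiters; with ``;`` or tab delimiters decimal
    commas are converted at ingest.  Column names must include the
    measurement field names (``L, tau, d_proximal_neck, r, R, D_AMAX`` and
    optionally ``L_AAA, d_distal_neck``); extra columns (e.g. a case label)
    are carried through.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"measurement file {path} is empty")
        return pd.DataFrame(columns=("case",) + _FIELDS)
    header = lines[0]
    if "\t" in header:
        sep = "\t"
    elif ";" in header:
        sep = ";"
    else:
        sep = ","
    reader = csv.reader(io.StringIO(text), delimiter=sep)
    rows = [row for row in reader if any(c.strip() for c in row)]
    columns = [c.strip() for c in rows[0]]
    records = []
    for row in rows[1:]:
        rec = {}
        for name, cell in zip(columns, row):
            if name in _FIELDS:
                rec[name] = _to_float(cell)
            else:
                rec[name] = cell.strip()
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=columns)


def measurements_from_row(row) -> VesselMeasurements:
    """Build a :class:`VesselMeasurements` from one table row (dict-like)."""
    kwargs = {}
    for name in _FIELDS:
        value = row.get(name) if hasattr(row, "get") else row[name]
        if value is not None and isinstance(value, float) and math.isnan(value):
            value = None
        if name in _REQUIRED and value is None:
            raise InvalidMeasurementError(name, "measurement is required")
        kwargs[name] = value
    return VesselMeasurements(**kwargs)
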