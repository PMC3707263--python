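"""Hemodynamic post-processing: wall shear stress, recirculation,
normalized pressure, cross-sections and per-case summaries.

Wall shear stress is the magnitude of the tangential part of the viscous
traction ``mu (grad u + grad u^T) . n`` evaluated from the wall-adjacent
element's (constant P1) velocity gradient.  Recirculation is defined by
the sign of the velocity component along the local centerline tangent:
the recirculation fraction is the portion of the sac volume (area in 2D)
where flow opposes the bulk direction.  All reported maps refer to the
peak-systole snapshot of the final simulated cycle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .fem import P1Basis
from .meshing import SimplexMesh, boundary_face_counts
from .solver import FlowField, FluidProperties, _boundary_flux
from .waveforms import InletGeometry, Waveform, reynolds_number

__all__ = [
    "WSSField",
    "HemodynamicSummary",
    "CrossSection",
    "compute_wss",
    "classify_wss",
    "recirculation_fraction",
    "normalized_pressure",
    "peak_systole_snapshot",
    "extract_cross_sections",
    "summarize",
]

LABEL_LOW = "low"
LABEL_HIGH = "high"


@dataclass
class WSSField:
    """Per-wall-facet wall shear stress magnitudes (Pa)."""

    values: np.ndarray          # (nw,) Pa, >= 0
    centroids: np.ndarray       # (nw, dim) facet centroids, m
    areas: np.ndarray           # (nw,) facet measures
    facet_ids: np.ndarray       # indices into mesh.facets
    labels: Optional[np.ndarray] = None   # "low"/"high" after classification
    threshold: Optional[float] = None     # Pa, the sac-mean cut

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.areas))

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass
class HemodynamicSummary:
    """Per-case scalar summary at the peak-systole snapshot."""

    sac_mean_wss: float
    sac_max_wss: float
    wall_mean_wss: float
    wss_cv: float                     # coefficient of variation over the wall
    recirculation_fraction: float
    recirculation_zones: int
    pressure_drop: float              # Pa, inlet minus outlet mean
    reynolds_inlet: float
    snapshot_time: float              # s
    neck_max_wss: float = math.nan
    low_wss_recirc_jaccard: float = math.nan


@dataclass
class CrossSection:
    """Velocity samples on a plane normal to the local centerline."""

    label: str
    point: np.ndarray
    normal: np.ndarray
    area: float
    centroid: np.ndarray
    flux_centroid: np.ndarray
    flux_centroid_offset: float
    sample_points: np.ndarray
    through_velocity: np.ndarray
    inplane_velocity: np.ndarray


def _wall_adjacency(mesh: SimplexMesh):
    mask = mesh.facet_mask("wall")
    ids = np.flatnonzero(mask)
    facets = mesh.facets[ids]
    owners = mesh.facet_elements[ids]
    measures = mesh.facet_measures(mask)
    normals = mesh.facet_normals(mask)
    centroids = mesh.points[facets].mean(axis=1)
    return ids, facets, owners, measures, normals, centroids


def compute_wss(
    field: FlowField,
    mesh: SimplexMesh,
    props: FluidProperties,
    t: float,
    basis: Optional[P1Basis] = None,
) -> WSSField:
    """Wall shear stress magnitude per wall facet at stored time ``t``."""
    if not np.any(mesh.facet_mask("wall")):
        raise ValueError("mesh has no wall facets")
    idx = field.at(t)
    u = field.u[idx]
    basis = basis or P1Basis(mesh)
    grad = basis.element_gradient(u)             # (ne, dim, dim): du_m/dx_d
    ids, facets, owners, measures, normals, centroids = _wall_adjacency(mesh)
    g = grad[owners]
    strain = g + np.transpose(g, (0, 2, 1))
    traction = props.dynamic_viscosity * np.einsum("eij,ej->ei", strain, normals)
    tn = np.einsum("ei,ei->e", traction, normals)
    tang = traction - tn[:, None] * normals
    wss = np.linalg.norm(tang, axis=1)
    return WSSField(
        values=wss, centroids=centroids, areas=measures, facet_ids=ids
    )


def _sac_mask_axial(coords_axial: np.ndarray, sac_region) -> np.ndarray:
    z0, z1 = sac_region
    return (coords_axial >= z0) & (coords_axial <= z1)


def classify_wss(wss: WSSField, sac_region: Optional[Tuple[float, float]]) -> WSSField:
    """Label wall facets low/high against the area-weighted sac-mean WSS.

    Facets at the threshold go to "high".  With no sac the whole wall
    defines the threshold (warned).
    """
    axial = wss.centroids[:, 0]
    if sac_region is None:
        warnings.warn("no sac region: classifying against the whole-wall mean")
        in_sac = np.ones(len(wss.values), dtype=bool)
    else:
        in_sac = _sac_mask_axial(axial, sac_region)
        if not np.any(in_sac):
            warnings.warn("empty sac region: classifying against the whole-wall mean")
            in_sac = np.ones(len(wss.values), dtype=bool)
    threshold = float(np.average(wss.values[in_sac], weights=wss.areas[in_sac]))
    labels = np.where(wss.values < threshold, LABEL_LOW, LABEL_HIGH)
    return WSSField(
        values=wss.values, centroids=wss.centroids, areas=wss.areas,
        facet_ids=wss.facet_ids, labels=labels, threshold=threshold,
    )


def _element_adjacency(mesh: SimplexMesh) -> sp.csr_matrix:
    nv = mesh.elements.shape[1]
    faces = []
    owners = []
    for k in range(nv):
        f = np.sort(mesh.elements[:, [j for j in range(nv) if j != k]], axis=1)
        faces.append(f)
        owners.append(np.arange(mesh.nelements))
    faces = np.concatenate(faces)
    owners = np.concatenate(owners)
    order = np.lexsort(faces.T[::-1])
    faces_s = faces[order]
    owners_s = owners[order]
    same = np.all(faces_s[1:] == faces_s[:-1], axis=1)
    a = owners_s[:-1][same]
    b = owners_s[1:][same]
    n = mesh.nelements
    return sp.coo_matrix(
        (np.ones(2 * len(a)), (np.concatenate([a, b]), np.concatenate([b, a]))),
        shape=(n, n),
    ).tocsr()


def recirculation_fraction(
    field: FlowField,
    mesh: SimplexMesh,
    sac_region: Optional[Tuple[float, float]],
    t: float,
    tangent: Optional[callable] = None,
) -> Tuple[float, int]:
    """Fraction of the sac where flow opposes the centerline direction.

    Returns ``(fraction, n_zones)`` with ``n_zones`` the number of
    face-connected reversed-flow components inside the sac.  ``tangent``
    maps axial coordinates to local centerline tangent vectors; the
    default is the straight +axial direction.
    """
    idx = field.at(t)
    u = field.u[idx]
    vols = np.abs(mesh.element_volumes())
    cent = mesh.points[mesh.elements].mean(axis=1)
    u_elem = u[mesh.elements].mean(axis=1)
    if tangent is None:
        tvec = np.zeros((mesh.nelements, mesh.dim))
        tvec[:, 0] = 1.0
    else:
        tvec = np.asarray(tangent(cent[:, 0]))
        tvec = tvec / np.linalg.norm(tvec, axis=1, keepdims=True)
    axial_comp = np.einsum("ij,ij->i", u_elem, tvec)
    if sac_region is None:
        in_sac = np.ones(mesh.nelements, dtype=bool)
    else:
        in_sac = _sac_mask_axial(cent[:, 0], sac_region)
    if not np.any(in_sac):
        return 0.0, 0
    reversed_mask = in_sac & (axial_comp < 0.0)
    frac = float(vols[reversed_mask].sum() / vols[in_sac].sum())
    n_zones = 0
    if np.any(reversed_mask):
        adj = _element_adjacency(mesh)
        sub = adj[reversed_mask][:, reversed_mask]
        n_zones, _ = connected_components(sub, directed=False)
    return frac, n_zones


def normalized_pressure(
    field: FlowField, t: float, wall_only: bool = True
) -> np.ndarray:
    """(p - p_min)/(p_max - p_min) over wall nodes at ``t``.

    A constant pressure field maps to all zeros by convention.
    """
    idx = field.at(t)
    p = field.p[idx]
    if wall_only:
        nodes = field.mesh.facet_nodes("wall")
    else:
        nodes = np.arange(field.mesh.npoints)
    pw = p[nodes]
    span = pw.max() - pw.min()
    if span <= 1e-300 * max(1.0, abs(pw.max())) or span == 0.0:
        return np.zeros(len(nodes))
    return (pw - pw.min()) / span


def peak_systole_snapshot(field: FlowField, w: Waveform) -> float:
    """Stored stamp nearest to peak systole of the final cycle.

    The reporting protocol runs at least two pulsatile cycles and reads
    all maps at ``(cycles - 1) * T + peak_time``; fewer than two simulated
    cycles is an error.
    """
    T = w.period
    t_total = field.times[-1]
    cycles = int(round(t_total / T))
    if cycles < 2:
        raise ValueError(
            "peak-systole reporting requires at least two simulated cycles "
            "(transients decay over the first cycle)"
        )
    target = (cycles - 1) * T + w.peak_time
    return float(field.times[field.at(target)])


def _plane_cut(mesh: SimplexMesh, point: np.ndarray, normal: np.ndarray,
               fields: List[np.ndarray]):
    """Intersect the mesh with a plane; return per-polygon areas,
    centroids, and linearly interpolated nodal fields at the cut points."""
    d = (mesh.points - point) @ normal
    elems = mesh.elements
    de = d[elems]
    cut = (de.min(axis=1) < 0) & (de.max(axis=1) > 0)
    if not np.any(cut) or np.any(de == 0.0):
        # plane coincides with a mesh station: nudge it off the nodes
        span = float(np.abs(d).max())
        d = d - 1e-7 * max(span, 1e-12)
        de = d[elems]
        cut = (de.min(axis=1) < 0) & (de.max(axis=1) > 0)
    polys = []
    interped = [[] for _ in fields]
    areas = []
    centroids = []
    nv = elems.shape[1]
    pairs = [(i, j) for i in range(nv) for j in range(i + 1, nv)]
    for e in np.flatnonzero(cut):
        verts = []
        vals = [[] for _ in fields]
        for i, j in pairs:
            di, dj = de[e, i], de[e, j]
            if (di < 0) != (dj < 0):
                s = di / (di - dj)
                ni, nj = elems[e, i], elems[e, j]
                verts.append(mesh.points[ni] + s * (mesh.points[nj] - mesh.points[ni]))
                for k, f in enumerate(fields):
                    vals[k].append(f[ni] + s * (f[nj] - f[ni]))
        if len(verts) < mesh.dim - 1 + 1 and mesh.dim == 3:
            continue
        verts = np.asarray(verts)
        if mesh.dim == 2:
            if len(verts) != 2:
                continue
            area = float(np.linalg.norm(verts[1] - verts[0]))
            centroid = verts.mean(axis=0)
        else:
            if len(verts) < 3:
                continue
            c0 = verts.mean(axis=0)
            ang = np.arctan2(
                (verts - c0) @ _perp(normal, 1), (verts - c0) @ _perp(normal, 0)
            )
            order = np.argsort(ang)
            verts = verts[order]
            vals = [[v[o] for o in order] for v in vals]
            area = 0.0
            centroid = np.zeros(3)
            for k in range(1, len(verts) - 1):
                tri_a = 0.5 * np.linalg.norm(
                    np.cross(verts[k] - verts[0], verts[k + 1] - verts[0])
                )
                area += tri_a
                centroid += tri_a * (verts[0] + verts[k] + verts[k + 1]) / 3.0
            if area <= 0:
                continue
            centroid /= area
        polys.append(verts)
        areas.append(area)
        centroids.append(centroid)
        for k in range(len(fields)):
            interped[k].append(np.mean(np.asarray(vals[k]), axis=0))
    return (
        polys,
        np.asarray(areas),
        np.asarray(centroids),
        [np.asarray(v) for v in interped],
    )


def _perp(normal: np.ndarray, which: int) -> np.ndarray:
    ref = np.zeros(3)
    ref[np.argmin(np.abs(normal))] = 1.0
    e0 = np.cross(normal, ref)
    e0 /= np.linalg.norm(e0)
    e1 = np.cross(normal, e0)
    return e0 if which == 0 else e1


def extract_cross_sections(
    field: FlowField,
    mesh: SimplexMesh,
    details: Dict,
    t: float,
) -> List[CrossSection]:
    """Cross-sections at the proximal neck, midsection and distal neck.

    ``details`` is the measurement detail dict from
    :func:`aaaflow.meshing.measure_geometry`; section planes are normal to
    the local centerline tangent there.
    """
    if details.get("sac_interval_m") is None:
        raise ValueError("no sac located: cross-section stations undefined")
    z0, z1 = details["sac_interval_m"]
    zm = details["z_mid_m"]
    stations = [("proximal neck", z0), ("midsection", zm), ("distal neck", z1)]
    zs = details["z_m"]
    axis_pts = details["axis_m"]
    tangents = details["tangent"]
    idx = field.at(t)
    u = field.u[idx]
    z_lo, z_hi = mesh.points[:, 0].min(), mesh.points[:, 0].max()
    out = []
    for label, z in stations:
        if not (z_lo - 1e-12 <= z <= z_hi + 1e-12):
            raise ValueError(f"station {label} at {z} m outside the mesh")
        k = int(np.argmin(np.abs(zs - z)))
        point = axis_pts[k].copy()
        point[0] = z
        normal = tangents[k]
        fields = [u[:, c] for c in range(mesh.dim)]
        polys, areas, cents, vals = _plane_cut(mesh, point, normal, fields)
        if len(areas) == 0:
            raise ValueError(f"station {label}: plane does not cut the mesh")
        uvec = np.stack(vals, axis=1)
        through = uvec @ normal
        inplane = uvec - np.outer(through, normal)
        area = float(areas.sum())
        centroid = (cents * areas[:, None]).sum(axis=0) / area
        flux = through * areas
        denom = flux.sum()
        if abs(denom) > 1e-300:
            flux_centroid = (cents * flux[:, None]).sum(axis=0) / denom
        else:
            flux_centroid = centroid.copy()
        offset = float(np.linalg.norm(
            (flux_centroid - centroid)
            - ((flux_centroid - centroid) @ normal) * normal
        ))
        out.append(CrossSection(
            label=label, point=point, normal=normal, area=area,
            centroid=centroid, flux_centroid=flux_centroid,
            flux_centroid_offset=offset, sample_points=cents,
            through_velocity=through, inplane_velocity=inplane,
        ))
    return out


def _mean_boundary_pressure(mesh: SimplexMesh, p: np.ndarray, name: str) -> float:
    mask = mesh.facet_mask(name)
    meas = mesh.facet_measures(mask)
    pv = p[mesh.facets[mask]].mean(axis=1)
    return float((pv * meas).sum() / meas.sum())


def low_wss_recirculation_overlap(
    wss: WSSField,
    field: FlowField,
    mesh: SimplexMesh,
    sac_region: Tuple[float, float],
    t: float,
) -> float:
    """Jaccard overlap of the axial extents of low-WSS wall area and
    reversed-flow volume inside the sac (station-discretized)."""
    if wss.labels is None:
        raise ValueError("classify_wss must run first")
    z0, z1 = sac_region
    bins = np.linspace(z0, z1, 25)
    axial_w = wss.centroids[:, 0]
    low = np.histogram(
        axial_w[(wss.labels == LABEL_LOW) & _sac_mask_axial(axial_w, sac_region)],
        bins=bins,
    )[0] > 0
    idx = field.at(t)
    u = field.u[idx]
    cent = mesh.points[mesh.elements].mean(axis=1)
    rev = u[mesh.elements].mean(axis=1)[:, 0] < 0
    mask = rev & _sac_mask_axial(cent[:, 0], sac_region)
    revbins = np.histogram(cent[mask, 0], bins=bins)[0] > 0
    union = np.sum(low | revbins)
    if union == 0:
        return 0.0
    return float(np.sum(low & revbins) / union)


def summarize(
    field: FlowField,
    mesh: SimplexMesh,
    details: Optional[Dict],
    props: FluidProperties,
    w: Waveform,
    tangent: Optional[callable] = None,
) -> HemodynamicSummary:
    """Assemble the per-case scalar summary at the peak-systole snapshot."""
    t = peak_systole_snapshot(field, w)
    idx = field.at(t)
    sac_region = None if details is None else details.get("sac_interval_m")
    wss = compute_wss(field, mesh, props, t)
    wss = classify_wss(wss, sac_region)
    if sac_region is not None:
        in_sac = _sac_mask_axial(wss.centroids[:, 0], sac_region)
    else:
        in_sac = np.ones(len(wss.values), dtype=bool)
    sac_mean = float(np.average(wss.values[in_sac], weights=wss.areas[in_sac]))
    sac_max = float(wss.values[in_sac].max()) if np.any(in_sac) else 0.0
    wall_mean = wss.mean
    # spatial uniformity measured away from the inlet/outlet bands (one
    # vessel diameter each): the imposed inlet profile differs from the
    # developed pulsatile one, an adjustment artifact, not sac physics
    geom0 = InletGeometry.from_mesh(mesh)
    d_ref = geom0.size
    z = wss.centroids[:, 0]
    z_lo, z_hi = z.min(), z.max()
    interior = (z > z_lo + d_ref) & (z < z_hi - d_ref)
    if not np.any(interior):
        interior = np.ones(len(z), dtype=bool)
    int_mean = float(np.average(wss.values[interior], weights=wss.areas[interior]))
    var = float(np.average((wss.values[interior] - int_mean) ** 2,
                           weights=wss.areas[interior]))
    cv = math.sqrt(var) / int_mean if int_mean > 0 else 0.0

    frac, zones = recirculation_fraction(field, mesh, sac_region, t, tangent)
    p = field.p[idx]
    dp = (_mean_boundary_pressure(mesh, p, "inlet")
          - _mean_boundary_pressure(mesh, p, "outlet"))

    q_in = abs(_boundary_flux(mesh, field.u[idx], "inlet"))
    U = q_in / geom0.area
    re = reynolds_number(max(U, 1e-300), geom0.area, geom0.perimeter,
                         props.kinematic_viscosity) if U > 0 else 0.0

    neck_max = math.nan
    jaccard = math.nan
    if sac_region is not None and details is not None:
        d_neck = details["neck_diam_m"]
        z0 = sac_region[0]
        neck_band = (wss.centroids[:, 0] >= z0 - d_neck) & (
            wss.centroids[:, 0] <= z0 + d_neck
        )
        if np.any(neck_band):
            neck_max = float(wss.values[neck_band].max())
        jaccard = low_wss_recirculation_overlap(wss, field, mesh, sac_region, t)

    return HemodynamicSummary(
        sac_mean_wss=sac_mean,
        sac_max_wss=sac_max,
        wall_mean_wss=wall_mean,
        wss_cv=cv,
        recirculation_fraction=frac,
        recirculation_zones=zones,
        pressure_drop=dp,
        reynolds_inlet=re,
        snapshot_time=t,
        neck_max_wss=neck_max,
        low_wss_recirc_jaccard=jaccard,
    )
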