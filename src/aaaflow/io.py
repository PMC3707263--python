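"""Plain-text mesh and field I/O: VTK XML (.vtu/.pvd) and Gmsh MSH 2.2.

Writers emit ASCII with 17 significant digits so coordinates round-trip
float64 exactly.  Boundary facets are stored in MSH files as lower-
dimensional elements whose physical tag is the facet tag (1 inlet,
2 outlet, 3 wall); volume elements carry physical tag 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .meshing import SimplexMesh, boundary_face_counts, TAG_NAMES

__all__ = ["write_vtu", "write_pvd", "write_msh", "read_msh"]

_VTK_TRI = 5
_VTK_TET = 10
_FMT = "%.17g"


def _fmt_array(a: np.ndarray, per_line: int = 1) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        flat = [" ".join(_FMT % v for v in row) for row in np.atleast_2d(a)]
    else:
        flat = [" ".join(str(int(v)) for v in row) for row in np.atleast_2d(a)]
    return "\n".join(flat)


def write_vtu(
    mesh: SimplexMesh,
    path,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> Path:
    """Write the mesh (and optional nodal/cell fields) as ASCII .vtu.

    Vector point data is padded to 3 components as VTK expects.
    """
    path = Path(path)
    pts = mesh.points
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    ncell = mesh.nelements
    ctype = _VTK_TRI if mesh.elements.shape[1] == 3 else _VTK_TET
    nv = mesh.elements.shape[1]

    chunks = []
    w = chunks.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("<UnstructuredGrid>")
    w(f'<Piece NumberOfPoints="{mesh.npoints}" NumberOfCells="{ncell}">')
    w("<Points>")
    w('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w(_fmt_array(pts))
    w("</DataArray>")
    w("</Points>")
    if point_data:
        w("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                ncomp = 1
            else:
                if arr.shape[1] == 2:
                    arr = np.column_stack([arr, np.zeros(len(arr))])
                ncomp = arr.shape[1]
            w(f'<DataArray type="Float64" Name="{name}" '
              f'NumberOfComponents="{ncomp}" format="ascii">')
            w(_fmt_array(arr))
            w("</DataArray>")
        w("</PointData>")
    if cell_data:
        w("<CellData>")
        for name, arr in cell_data.items():
            w(f'<DataArray type="Float64" Name="{name}" '
              f'NumberOfComponents="1" format="ascii">')
            w(_fmt_array(np.asarray(arr, dtype=float)))
            w("</DataArray>")
        w("</CellData>")
    w("<Cells>")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w(_fmt_array(mesh.elements))
    w("</DataArray>")
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(_fmt_array(np.arange(1, ncell + 1)[:, None] * nv))
    w("</DataArray>")
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(_fmt_array(np.full((ncell, 1), ctype)))
    w("</DataArray>")
    w("</Cells>")
    w("</Piece>")
    w("</UnstructuredGrid>")
    w("</VTKFile>")
    path.write_text("\n".join(chunks))
    return path


def write_pvd(path, times, vtu_paths) -> Path:
    """Write a ParaView collection referencing a VTU time series."""
    path = Path(path)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1">',
        "<Collection>",
    ]
    for t, p in zip(times, vtu_paths):
        lines.append(f'<DataSet timestep="{_FMT % t}" file="{Path(p).name}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


_MSH_TYPE = {2: 1, 3: 2, 4: 4}  # node count -> gmsh element type


def write_msh(mesh: SimplexMesh, path) -> Path:
    """Write the tagged mesh in Gmsh MSH 2.2 ASCII format."""
    path = Path(path)
    dim = mesh.dim
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    names = [(dim - 1, tag, name) for tag, name in TAG_NAMES.items()]
    names.append((dim, 0, "lumen"))
    lines.append(str(len(names)))
    for d, tag, name in names:
        lines.append(f'{d} {tag} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.npoints))
    for i, p in enumerate(mesh.points, start=1):
        coords = list(p) + [0.0] * (3 - dim)
        lines.append(f"{i} " + " ".join(_FMT % c for c in coords))
    lines.append("$EndNodes")
    lines.append("$Elements")
    nelem = len(mesh.facets) + mesh.nelements
    lines.append(str(nelem))
    eid = 1
    ftyp = _MSH_TYPE[mesh.facets.shape[1]]
    for f, tag in zip(mesh.facets, mesh.facet_tags):
        conn = " ".join(str(v + 1) for v in f)
        lines.append(f"{eid} {ftyp} 2 {tag} {tag} {conn}")
        eid += 1
    etyp = _MSH_TYPE[mesh.elements.shape[1]]
    for e in mesh.elements:
        conn = " ".join(str(v + 1) for v in e)
        lines.append(f"{eid} {etyp} 2 0 0 {conn}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines))
    return path


def read_msh(path) -> SimplexMesh:
    """Read a Gmsh MSH 2.2 ASCII mesh with tagged boundary facets."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)

    def seek(section):
        for ln in it:
            if ln.strip() == section:
                return True
        return False

    if not seek("$Nodes"):
        raise ValueError("not a MSH 2.2 file: no $Nodes section")
    n = int(next(it))
    coords = np.empty((n, 3))
    for k in range(n):
        parts = next(it).split()
        coords[int(parts[0]) - 1] = [float(v) for v in parts[1:4]]
    if not seek("$Elements"):
        raise ValueError("no $Elements section")
    ne = int(next(it))
    facets, tags, cells = [], [], []
    for _ in range(ne):
        parts = next(it).split()
        etyp = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags else 0
        conn = [int(v) - 1 for v in parts[3 + ntags:]]
        if etyp in (2, 4) and (etyp == 4 or phys == 0):
            cells.append(conn)
        elif etyp in (1, 2):
            facets.append(conn)
            tags.append(phys)
        else:
            raise ValueError(f"unsupported element type {etyp}")
    cells = np.asarray(cells, dtype=np.int64)
    dim = 3 if cells.shape[1] == 4 else 2
    points = coords[:, :dim]

    uniq, counts, owners = boundary_face_counts(cells)
    key = {tuple(f): o for f, o in zip(uniq[counts == 1], owners[counts == 1])}
    facets = np.asarray(facets, dtype=np.int64)
    facet_elements = np.array(
        [key[tuple(sorted(f))] for f in facets], dtype=np.int64
    )
    return SimplexMesh(
        points=points,
        elements=cells,
        facets=facets,
        facet_tags=np.asarray(tags, dtype=np.int64),
        facet_elements=facet_elements,
    )
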