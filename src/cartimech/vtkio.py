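"""Minimal ASCII VTK XML (.vtu) and STL writers/readers.

Covers exactly what this package emits: unstructured grids of hex8/tet4
cells with named point/cell data arrays, and triangulated surfaces. The
reader only guarantees round-tripping of files written here.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np

from .meshes import SurfaceMesh, VolumeMesh

_VTK_CELL = {"hex8": 12, "tet4": 10}
_CELL_NODES = {"hex8": 8, "tet4": 4}


def _data_array(name: str, arr: np.ndarray) -> str:
    arr = np.asarray(arr)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
    body = " ".join(f"{v:.17g}" if dtype == "Float64" else str(int(v)) for v in arr.ravel())
    return (
        f'<DataArray type="{dtype}" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n{body}\n</DataArray>\n'
    )


def write_vtu(path, mesh: VolumeMesh, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    point_data = {**mesh.point_data, **(point_data or {})}
    cell_data = {**mesh.cell_data, **(cell_data or {})}
    n_pts, n_cells = mesh.n_points, mesh.n_cells
    nn = _CELL_NODES[mesh.cell_type]
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n',
        "<Points>\n",
        _data_array("Points", mesh.points),
        "</Points>\n<Cells>\n",
        _data_array("connectivity", mesh.cells.astype(np.int64)),
        _data_array("offsets", np.arange(1, n_cells + 1, dtype=np.int64) * nn),
        _data_array("types", np.full(n_cells, _VTK_CELL[mesh.cell_type], dtype=np.int64)),
        "</Cells>\n",
    ]
    parts.append("<PointData>\n")
    for name, arr in point_data.items():
        parts.append(_data_array(name, arr))
    parts.append("</PointData>\n<CellData>\n")
    cell_data = {"material_id": mesh.material_id, **cell_data}
    for name, arr in cell_data.items():
        parts.append(_data_array(name, arr))
    parts.append("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))


def read_vtu(path) -> VolumeMesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        dtype = float if da.get("type") == "Float64" else int
        flat = np.array(da.text.split(), dtype=dtype)
        ncomp = int(da.get("NumberOfComponents", "1"))
        return flat if ncomp == 1 else flat.reshape(-1, ncomp)

    pts = parse(piece.find("Points/DataArray"))
    cells_el = {da.get("Name"): parse(da) for da in piece.findall("Cells/DataArray")}
    types = cells_el["types"]
    cell_type = "hex8" if types[0] == 12 else "tet4"
    conn = cells_el["connectivity"].reshape(-1, _CELL_NODES[cell_type])
    point_data = {da.get("Name"): parse(da) for da in piece.findall("PointData/DataArray")}
    cell_data = {da.get("Name"): parse(da) for da in piece.findall("CellData/DataArray")}
    mat = cell_data.pop("material_id", None)
    return VolumeMesh(
        points=pts, cells=conn, cell_type=cell_type,
        material_id=None if mat is None else mat.astype(int),
        point_data=point_data, cell_data=cell_data,
    )


def write_stl(path, surf: SurfaceMesh, name: str = "surface") -> None:
    """ASCII STL; quads are split into two triangles."""
    faces = surf.faces
    if faces.shape[1] == 4:
        faces = np.vstack([faces[:, [0, 1, 2]], faces[:, [0, 2, 3]]])
    p = surf.points
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for tri in faces:
            a, b, c = p[tri]
            n = np.cross(b - a, c - a)
            nrm = np.linalg.norm(n)
            n = n / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
            fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n    outer loop\n")
            for v in (a, b, c):
                fh.write(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {name}\n")
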