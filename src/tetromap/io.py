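"""Mesh, field and V_m file input/output.

Supported mesh dialects:

* CARP-style plain text: ``.pts`` (count header, then ``x y z`` per line;
  an optional first-line ``#mm``/``#um`` flag sets units, default um as in
  CARP) and ``.elem`` (count header, then ``Tt n0 n1 n2 n3 tag`` per line,
  0-based; 1-based files can be converted on read).
* A minimal ASCII VTK unstructured-grid ``.vtu`` (XML) writer/reader for
  tetrahedra, carrying ``region_tag``/``medium_id`` and arbitrary
  per-element scalar fields as CellData.  Written files round-trip their
  text fields exactly.

No third-party VTK reader is required; the subset emitted here is plain
XML handled with the standard library.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import TetMesh


class ParseError(ValueError):
    """Malformed mesh/field file; message names the offending line."""


# ---------------------------------------------------------------------------
# CARP-style .pts / .elem
# ---------------------------------------------------------------------------

def write_pts(path, mesh: TetMesh, units: str = "mm") -> None:
    scale = 1.0 if units == "mm" else 1000.0
    with open(path, "w") as f:
        f.write(f"#{units}\n{mesh.n_nodes}\n")
        for x, y, z in mesh.nodes * scale:
            f.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def write_elem(path, mesh: TetMesh) -> None:
    with open(path, "w") as f:
        f.write(f"{mesh.n_elements}\n")
        for (a, b, c, d), t in zip(mesh.elements, mesh.region_tag):
            f.write(f"Tt {a} {b} {c} {d} {t}\n")


def read_carp(pts_path, elem_path, tag_to_medium: dict[int, int] | None = None,
              one_based: bool = False) -> TetMesh:
    """Read a CARP-style mesh; tags map through `tag_to_medium` (identity
    by default).  Set ``one_based`` for files with 1-based node indices."""
    pts_path, elem_path = Path(pts_path), Path(elem_path)
    lines = pts_path.read_text().splitlines()
    i = 0
    units = "um"
    if lines and lines[0].startswith("#"):
        units = lines[0][1:].strip() or "um"
        i = 1
    try:
        n = int(lines[i])
    except (IndexError, ValueError):
        raise ParseError(f"{pts_path}:{i + 1}: expected node count")
    coords = np.empty((n, 3))
    for k in range(n):
        parts = lines[i + 1 + k].split()
        if len(parts) != 3:
            raise ParseError(f"{pts_path}:{i + 2 + k}: expected 'x y z'")
        coords[k] = [float(v) for v in parts]
    if units == "um":
        coords /= 1000.0

    elines = elem_path.read_text().splitlines()
    try:
        m = int(elines[0])
    except (IndexError, ValueError):
        raise ParseError(f"{elem_path}:1: expected element count")
    elems = np.empty((m, 4), dtype=np.int64)
    tags = np.empty(m, dtype=np.int64)
    for k in range(m):
        parts = elines[1 + k].split()
        if len(parts) != 6 or parts[0] != "Tt":
            raise ParseError(
                f"{elem_path}:{k + 2}: expected 'Tt n0 n1 n2 n3 tag'")
        elems[k] = [int(v) for v in parts[1:5]]
        tags[k] = int(parts[5])
    if one_based:
        elems -= 1
    if tag_to_medium is None:
        medium = tags.copy()
    else:
        medium = np.array([tag_to_medium[int(t)] for t in tags])
    return TetMesh(nodes=coords, elements=elems, region_tag=tags,
                   medium_id=medium)


# ---------------------------------------------------------------------------
# ASCII .vtu (VTK unstructured grid, tetrahedra only)
# ---------------------------------------------------------------------------

def write_vtu(path, mesh: TetMesh,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write an ASCII .vtu with region/medium tags plus extra cell fields."""
    m = mesh.n_elements
    fields = {"region_tag": mesh.region_tag, "medium_id": mesh.medium_id}
    if cell_data:
        fields.update(cell_data)
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{m}">\n')
        f.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3" '
                'format="ascii">\n')
        for x, y, z in mesh.nodes:
            f.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        f.write("</DataArray>\n</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for row in mesh.elements:
            f.write(" ".join(str(v) for v in row) + "\n")
        f.write("</DataArray>\n")
        f.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(4 * (i + 1)) for i in range(m)) + "\n")
        f.write("</DataArray>\n")
        f.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join("10" for _ in range(m)) + "\n")
        f.write("</DataArray>\n</Cells>\n<CellData>\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            typ = "Float64" if arr.dtype.kind == "f" else "Int64"
            f.write(f'<DataArray type="{typ}" Name="{name}" format="ascii">\n')
            if typ == "Float64":
                f.write("\n".join(repr(float(v)) for v in arr) + "\n")
            else:
                f.write("\n".join(str(int(v)) for v in arr) + "\n")
            f.write("</DataArray>\n")
        f.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def read_vtu(path) -> tuple[TetMesh, dict[str, np.ndarray]]:
    """Read a tetrahedral ASCII .vtu written by :func:`write_vtu` (or any
    ascii-format tet-only file).  Returns the mesh and all CellData fields."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ParseError(f"{path}: no <Piece> element")
    pts = piece.find("./Points/DataArray")
    coords = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("./Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=np.int64)
    if not np.all(types == 10):
        raise ParseError(f"{path}: unsupported cell type (tetrahedra only)")
    elems = conn.reshape(-1, 4)
    cell_data = {}
    cd = piece.find("./CellData")
    if cd is not None:
        for da in cd.findall("./DataArray"):
            kind = float if da.get("type", "").startswith("Float") else np.int64
            cell_data[da.get("Name")] = np.fromstring(da.text, sep=" ",
                                                      dtype=kind)
    region = cell_data.pop("region_tag", np.zeros(len(elems), dtype=np.int64))
    medium = cell_data.pop("medium_id", region.copy())
    mesh = TetMesh(nodes=coords, elements=elems,
                   region_tag=np.asarray(region, dtype=np.int64),
                   medium_id=np.asarray(medium, dtype=np.int64))
    return mesh, cell_data


def read_mesh(path, dialect: str | None = None, **kw) -> TetMesh:
    """Dispatch on dialect / extension: 'vtu' or 'carp' (pts+elem pair)."""
    path = Path(path)
    if dialect is None:
        dialect = "vtu" if path.suffix == ".vtu" else "carp"
    if dialect == "vtu":
        return read_vtu(path)[0]
    if dialect == "carp":
        return read_carp(path.with_suffix(".pts"), path.with_suffix(".elem"), **kw)
    raise ValueError(f"unknown mesh dialect {dialect!r}")


# ---------------------------------------------------------------------------
# V_m fields: wide CSV and raw binary + JSON sidecar
# ---------------------------------------------------------------------------

def write_vm_csv(path, times: np.ndarray, values: np.ndarray) -> None:
    """Wide CSV: header ``t,node0,node1,...``; one row per frame."""
    n = values.shape[1]
    header = "t," + ",".join(f"node{i}" for i in range(n))
    with open(path, "w") as f:
        f.write(header + "\n")
        for t, row in zip(times, values):
            f.write(f"{float(t)!r},"
                    + ",".join(repr(float(v)) for v in row) + "\n")


def read_vm_csv(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    return data[:, 0].copy(), data[:, 1:].copy()


def write_vm_binary(path, times: np.ndarray, values: np.ndarray) -> None:
    """Flat float64 binary (frames x nodes, C order) + JSON sidecar."""
    path = Path(path)
    np.asarray(values, dtype="<f8").tofile(path)
    sidecar = {"n_nodes": int(values.shape[1]),
               "times_ms": [float(t) for t in times]}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_vm_binary(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    times = np.asarray(meta["times_ms"], dtype=float)
    values = np.fromfile(path, dtype="<f8").reshape(len(times), meta["n_nodes"])
    return times, values
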