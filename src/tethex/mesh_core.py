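"""Mesh containers and file I/O.

The toolkit works on three element families: 4-node tetrahedra, 8-node
hexahedra and 3/4-node surface shells, plus 2-node beams for muscles and
ligaments.  Coordinates are millimetres throughout.  Node ids are 1-based in
every file dialect; internally connectivity is contiguous and 0-based, with
the original file ids preserved in ``node_ids``.

Hexahedra use the common 8-node brick convention: nodes 0-3 form the bottom
quadrilateral counter-clockwise (seen from above / from inside the element
looking toward the top face), nodes 4-7 the top quadrilateral, node 4 above
node 0.  All quality and volume code in the package assumes this ordering;
meshes whose corner Jacobians come out negative on read are re-ordered.

Supported dialects: legacy ASCII VTK unstructured grids, ASCII/binary STL
(triangles, via :mod:`trimesh`), Abaqus-style ``.inp`` (``*NODE`` /
``*ELEMENT`` sections) and LS-DYNA keyword ``.k`` (``*NODE``,
``*ELEMENT_SOLID``, ``*ELEMENT_SHELL``, ``*ELEMENT_BEAM``, ``*PART``).
Material, contact and control cards are never parsed; the keyword writer
emits them only as comments.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "MeshError",
    "MeshParseError",
    "UnsupportedElementError",
    "TetMesh",
    "HexMesh",
    "SurfaceMesh",
    "BeamSet",
    "read_mesh",
    "write_mesh",
    "boundary_surface",
    "enumerate_edges_faces",
    "mesh_volume",
]


class MeshError(ValueError):
    """Invalid mesh content (bad connectivity, non-finite coordinates...)."""


class MeshParseError(MeshError):
    """A file could not be parsed under the named dialect."""


class UnsupportedElementError(MeshError):
    """The file contains an element type the toolkit does not model."""


# faces of the standard 8-node brick, outward-oriented for a positive element
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # bottom
        [4, 5, 6, 7],  # top
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)

# outward faces of a positively oriented tetrahedron
TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])

TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
HEX_EDGES = np.array(
    [[0, 1], [1, 2], [2, 3], [3, 0],
     [4, 5], [5, 6], [6, 7], [7, 4],
     [0, 4], [1, 5], [2, 6], [3, 7]]
)

# at each brick corner, the three adjacent corners ordered so that the edge
# triple is right-handed on the unit cube (determinant +1)
HEX_CORNER_NEIGHBORS = np.array(
    [[1, 3, 4], [2, 0, 5], [3, 1, 6], [0, 2, 7],
     [7, 5, 0], [4, 6, 1], [5, 7, 2], [6, 4, 3]]
)


def _as_points(nodes: np.ndarray) -> np.ndarray:
    pts = np.asarray(nodes, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MeshError(f"node array must be (n, 3), got {pts.shape}")
    if not np.isfinite(pts).all():
        raise MeshError("non-finite node coordinates")
    return pts


def _as_elements(elements: np.ndarray, width: int, n_nodes: int) -> np.ndarray:
    elems = np.asarray(elements, dtype=np.int64)
    if elems.size == 0:
        return elems.reshape(0, width)
    if elems.ndim != 2 or elems.shape[1] != width:
        raise MeshError(f"element array must be (n, {width}), got {elems.shape}")
    if elems.min() < 0 or elems.max() >= n_nodes:
        raise MeshError("element connectivity references a missing node")
    return elems


def _default_ids(n: int) -> np.ndarray:
    return np.arange(1, n + 1, dtype=np.int64)


@dataclass
class _Mesh:
    nodes: np.ndarray
    elements: np.ndarray
    part_label: str = ""
    node_ids: np.ndarray = field(default=None)  # original 1-based file ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        """(n_elements, nodes_per_element, 3) coordinate array."""
        return self.nodes[self.elements]


class TetMesh(_Mesh):
    """Unstructured first-order tetrahedral volume mesh.

    On construction every element is re-ordered, if needed, so its signed
    volume is positive (swap of the last two nodes).
    """

    def __init__(self, nodes, elements, part_label: str = "", node_ids=None):
        nodes = _as_points(nodes)
        elements = _as_elements(elements, 4, len(nodes))
        vol = _tet_signed_volumes(nodes, elements)
        flip = vol < 0
        if flip.any():
            elements = elements.copy()
            elements[flip] = elements[flip][:, [0, 1, 3, 2]]
        super().__init__(nodes, elements, part_label,
                         _default_ids(len(nodes)) if node_ids is None else np.asarray(node_ids))


class HexMesh(_Mesh):
    """Unstructured 8-node hexahedral volume mesh (standard brick ordering).

    Elements whose corner-0 Jacobian is negative are flipped (orientation
    reversal that keeps the brick convention).
    """

    def __init__(self, nodes, elements, part_label: str = "", node_ids=None):
        nodes = _as_points(nodes)
        elements = _as_elements(elements, 8, len(nodes))
        if len(elements):
            p = nodes[elements]
            e1 = p[:, 1] - p[:, 0]
            e3 = p[:, 3] - p[:, 0]
            e4 = p[:, 4] - p[:, 0]
            det = np.einsum("ij,ij->i", np.cross(e1, e3), e4)
            flip = det < 0
            if flip.any():
                elements = elements.copy()
                elements[flip] = elements[flip][:, [0, 3, 2, 1, 4, 7, 6, 5]]
        super().__init__(nodes, elements, part_label,
                         _default_ids(len(nodes)) if node_ids is None else np.asarray(node_ids))


class SurfaceMesh(_Mesh):
    """Triangulated or quadrilateral surface shell (homogeneous face kind)."""

    def __init__(self, nodes, faces, part_label: str = "", node_ids=None):
        nodes = _as_points(nodes)
        faces = np.asarray(faces, dtype=np.int64)
        width = faces.shape[1] if faces.ndim == 2 else 3
        if width not in (3, 4):
            raise MeshError("surface faces must be triangles or quads")
        faces = _as_elements(faces, width, len(nodes))
        super().__init__(nodes, faces, part_label,
                         _default_ids(len(nodes)) if node_ids is None else np.asarray(node_ids))

    @property
    def faces(self) -> np.ndarray:
        return self.elements

    @property
    def face_kind(self) -> str:
        return "triangle" if self.elements.shape[1] == 3 else "quad"


@dataclass
class BeamSet:
    """Two-node beam elements standing in for muscles or ligaments."""

    elements: np.ndarray
    kind: Literal["muscle", "ligament"] = "ligament"
    property_ref: str = ""

    def __post_init__(self):
        elems = np.asarray(self.elements, dtype=np.int64).reshape(-1, 2)
        if len(elems) and (elems[:, 0] == elems[:, 1]).any():
            raise MeshError("beam element with two identical nodes")
        self.elements = elems


# ---------------------------------------------------------------------------
# geometry helpers

def _tet_signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    if len(elements) == 0:
        return np.zeros(0)
    p = nodes[elements]
    return np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    ) / 6.0


def _hex_signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed hex volumes by fanning tets from the element centroid.

    Each of the 6 quad faces is split into two triangles; with the face
    centroid this is exact for non-planar faces as well (the bilinear face is
    approximated consistently for writer/reader symmetry).
    """
    if len(elements) == 0:
        return np.zeros(0)
    p = nodes[elements]  # (n, 8, 3)
    c = p.mean(axis=1)  # element centroid
    vol = np.zeros(len(elements))
    for face in HEX_FACES:
        q = p[:, face]  # (n, 4, 3)
        fc = q.mean(axis=1)
        for a, b in ((0, 1), (1, 2), (2, 3), (3, 0)):
            vol += np.einsum(
                "ij,ij->i", np.cross(q[:, a] - c, q[:, b] - c), fc - c
            ) / 6.0
    return vol


def mesh_volume(mesh: TetMesh | HexMesh) -> float:
    """Total mesh volume in mm^3 (sum of signed element volumes).

    Inverted elements contribute their signed volume and trigger a warning
    naming them.
    """
    if isinstance(mesh, TetMesh):
        vols = _tet_signed_volumes(mesh.nodes, mesh.elements)
    elif isinstance(mesh, HexMesh):
        vols = _hex_signed_volumes(mesh.nodes, mesh.elements)
    else:
        raise TypeError("mesh_volume expects a TetMesh or HexMesh")
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        warnings.warn(f"{bad.size} inverted element(s), e.g. element {bad[0]}; "
                      "signed contribution kept")
    return float(vols.sum())


def enumerate_edges_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges and triangular faces of a tet mesh.

    Canonical key is the sorted node-id tuple, so the result is independent
    of per-element node order.  Returns ``(edges (E,2), faces (F,3))`` sorted
    lexicographically.
    """
    if mesh.n_elements == 0:
        return np.zeros((0, 2), dtype=np.int64), np.zeros((0, 3), dtype=np.int64)
    edges = np.sort(mesh.elements[:, TET_EDGES].reshape(-1, 2), axis=1)
    faces = np.sort(mesh.elements[:, TET_FACES].reshape(-1, 3), axis=1)
    return np.unique(edges, axis=0), np.unique(faces, axis=0)


def boundary_surface(mesh: TetMesh | HexMesh) -> SurfaceMesh:
    """Outward-oriented boundary of a volume mesh.

    A face is on the boundary iff it belongs to exactly one element.  Face
    orientation is taken from the owning (positively oriented) element, so
    normals point out of the body.
    """
    if isinstance(mesh, TetMesh):
        local = TET_FACES
    elif isinstance(mesh, HexMesh):
        local = HEX_FACES
    else:
        raise TypeError("boundary_surface expects a TetMesh or HexMesh")
    width = local.shape[1]
    faces = mesh.elements[:, local].reshape(-1, width)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    keep = counts[inverse] == 1
    bfaces = faces[keep]
    return SurfaceMesh(mesh.nodes, bfaces, part_label=mesh.part_label)


def surface_used_nodes(surface: SurfaceMesh) -> np.ndarray:
    """Indices of the nodes actually referenced by a surface's faces."""
    return np.unique(surface.faces)


# ---------------------------------------------------------------------------
# readers / writers

_FORMATS = ("vtk", "stl", "inp", "keyword")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    return {".vtk": "vtk", ".stl": "stl", ".inp": "inp", ".k": "keyword",
            ".key": "keyword", ".dyn": "keyword"}.get(ext, "")


def read_mesh(path: str | os.PathLike, format: str | None = None):
    """Read a mesh file, returning a TetMesh, HexMesh or SurfaceMesh.

    ``format`` is one of ``vtk|stl|inp|keyword``; inferred from the file
    extension when omitted.  Mixed element families in one file are not
    modelled — the file must contain a single family.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "stl":
        return _read_stl(path)
    if fmt == "inp":
        return _read_inp(path)
    return _read_keyword(path)


def write_mesh(mesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a mesh; the emitted file re-reads to an equivalent mesh."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "stl":
        if not (isinstance(mesh, SurfaceMesh) and mesh.face_kind == "triangle"):
            raise UnsupportedElementError("STL holds triangle surfaces only")
        _write_stl(mesh, path)
    elif fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "inp":
        _write_inp(mesh, path)
    else:
        _write_keyword(mesh, path)


def _mesh_from_cells(nodes, cells, width, label, node_ids=None):
    if width == 4 and cells.get("kind") == "tet":
        return TetMesh(nodes, cells["conn"], label, node_ids)
    if width == 8:
        return HexMesh(nodes, cells["conn"], label, node_ids)
    return SurfaceMesh(nodes, cells["conn"], label, node_ids)


# -- legacy VTK -------------------------------------------------------------

_VTK_CELL = {10: ("tet", 4), 12: ("hex", 8), 5: ("tri", 3), 9: ("quad", 4)}
_VTK_CODE = {"tet": 10, "hex": 12, "tri": 5, "quad": 9}


def _read_vtk(path: Path):
    lines = path.read_text().splitlines()
    tokens: list[str] = []
    it = iter(enumerate(lines, 1))
    try:
        header = [next(it), next(it), next(it), next(it)]
    except StopIteration:
        raise MeshParseError(f"{path}: truncated VTK header")
    if "ASCII" not in header[2][1].upper():
        raise MeshParseError(f"{path}:3: only ASCII legacy VTK is supported")
    if "UNSTRUCTURED_GRID" not in header[3][1].upper():
        raise MeshParseError(f"{path}:4: expected DATASET UNSTRUCTURED_GRID")
    body = lines[4:]
    idx = 0

    def next_section(name):
        nonlocal idx
        while idx < len(body) and not body[idx].strip():
            idx += 1
        if idx >= len(body) or not body[idx].upper().startswith(name):
            raise MeshParseError(f"{path}:{idx + 5}: expected {name} section")
        line = body[idx].split()
        idx += 1
        return line

    n_pts = int(next_section("POINTS")[1])
    vals: list[float] = []
    while len(vals) < 3 * n_pts:
        vals.extend(float(v) for v in body[idx].split())
        idx += 1
    nodes = np.array(vals, dtype=float).reshape(n_pts, 3)

    cells_hdr = next_section("CELLS")
    n_cells, n_ints = int(cells_hdr[1]), int(cells_hdr[2])
    ints: list[int] = []
    while len(ints) < n_ints:
        ints.extend(int(v) for v in body[idx].split())
        idx += 1
    types_hdr = next_section("CELL_TYPES")
    tvals: list[int] = []
    while len(tvals) < int(types_hdr[1]):
        tvals.extend(int(v) for v in body[idx].split())
        idx += 1

    conn, pos, kinds = [], 0, set()
    for code in tvals:
        npts = ints[pos]
        cell = ints[pos + 1: pos + 1 + npts]
        pos += npts + 1
        if code not in _VTK_CELL:
            raise UnsupportedElementError(f"{path}: VTK cell type {code} not supported")
        kind, width = _VTK_CELL[code]
        kinds.add(kind)
        conn.append(cell)
    if len(kinds) > 1:
        raise UnsupportedElementError(f"{path}: mixed cell families {sorted(kinds)}")
    kind = kinds.pop() if kinds else "tet"
    arr = np.array(conn, dtype=np.int64).reshape(len(conn), -1) if conn else np.zeros((0, 4), np.int64)
    return _mesh_from_cells(nodes, {"kind": kind, "conn": arr},
                            arr.shape[1] if len(conn) else 4, path.stem)


def _write_vtk(mesh, path: Path) -> None:
    if isinstance(mesh, TetMesh):
        kind = "tet"
    elif isinstance(mesh, HexMesh):
        kind = "hex"
    elif isinstance(mesh, SurfaceMesh):
        kind = mesh.face_kind if mesh.face_kind != "triangle" else "tri"
    else:
        raise TypeError(f"cannot write {type(mesh).__name__} to VTK")
    elems = mesh.elements
    width = elems.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.part_label or 'tethex mesh'}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {len(elems)} {len(elems) * (width + 1)}\n")
        block = np.column_stack([np.full(len(elems), width, dtype=np.int64), elems])
        np.savetxt(fh, block, fmt="%d")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        np.savetxt(fh, np.full(len(elems), _VTK_CODE[kind], dtype=np.int64), fmt="%d")


# -- STL (via trimesh) ------------------------------------------------------

def _read_stl(path: Path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="stl", process=True)
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshParseError(f"{path}: not a triangle STL body")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64),
                       part_label=path.stem)


def _write_stl(mesh: SurfaceMesh, path: Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.faces, process=False)
    tm.export(str(path), file_type="stl_ascii")


# -- Abaqus-style .inp ------------------------------------------------------

_INP_TYPES = {"C3D4": ("tet", 4), "C3D8": ("hex", 8), "C3D8R": ("hex", 8),
              "S3": ("tri", 3), "S3R": ("tri", 3), "S4": ("quad", 4), "S4R": ("quad", 4)}


def _read_inp(path: Path):
    nodes_raw: list[tuple[int, float, float, float]] = []
    conn_raw: list[list[int]] = []
    kind = None
    section = None
    label = path.stem
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("**"):
            continue
        if s.startswith("*"):
            upper = s.upper()
            if upper.startswith("*NODE"):
                section = "node"
            elif upper.startswith("*ELEMENT"):
                typ = ""
                for fieldtok in s.split(",")[1:]:
                    k, _, v = fieldtok.partition("=")
                    if k.strip().upper() == "TYPE":
                        typ = v.strip().upper()
                if typ not in _INP_TYPES:
                    raise UnsupportedElementError(f"{path}:{ln}: element type {typ or '?'} not supported")
                k2, _ = _INP_TYPES[typ]
                if kind is not None and k2 != kind:
                    raise UnsupportedElementError(f"{path}:{ln}: mixed element families")
                kind = k2
                section = "element"
            else:
                section = None
            continue
        parts = [p for p in s.replace(",", " ").split()]
        try:
            if section == "node":
                nodes_raw.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
            elif section == "element":
                conn_raw.append([int(p) for p in parts])
        except (ValueError, IndexError):
            raise MeshParseError(f"{path}:{ln}: malformed data line {s!r}")
    return _assemble_id_based(nodes_raw, conn_raw, kind, label, path)


def _assemble_id_based(nodes_raw, conn_raw, kind, label, path):
    if not nodes_raw:
        raise MeshParseError(f"{path}: no nodes found")
    ids = np.array([n[0] for n in nodes_raw], dtype=np.int64)
    if len(np.unique(ids)) != len(ids):
        raise MeshParseError(f"{path}: duplicate node ids")
    coords = np.array([n[1:] for n in nodes_raw], dtype=float)
    order = np.argsort(ids)
    ids, coords = ids[order], coords[order]
    id_to_idx = {int(i): k for k, i in enumerate(ids)}
    if not conn_raw:
        raise MeshParseError(f"{path}: no elements found")
    width = {"tet": 4, "hex": 8, "tri": 3, "quad": 4}[kind]
    conn = np.empty((len(conn_raw), width), dtype=np.int64)
    for r, row in enumerate(conn_raw):
        body = row[1:]  # drop element id
        try:
            conn[r] = [id_to_idx[n] for n in body[:width]]
        except KeyError as exc:
            raise MeshParseError(f"{path}: element references unknown node {exc}")
    return _mesh_from_cells(coords, {"kind": kind, "conn": conn}, width, label, node_ids=ids)


def _write_inp(mesh, path: Path) -> None:
    if isinstance(mesh, TetMesh):
        typ = "C3D4"
    elif isinstance(mesh, HexMesh):
        typ = "C3D8"
    elif isinstance(mesh, SurfaceMesh):
        typ = "S3" if mesh.face_kind == "triangle" else "S4"
    else:
        raise TypeError(f"cannot write {type(mesh).__name__} to .inp")
    with open(path, "w") as fh:
        fh.write(f"*HEADING\n** {mesh.part_label or 'tethex mesh'}\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, 1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        fh.write(f"*ELEMENT, TYPE={typ}\n")
        for e, row in enumerate(mesh.elements + 1, 1):
            fh.write(f"{e}, " + ", ".join(str(n) for n in row) + "\n")


# -- LS-DYNA keyword --------------------------------------------------------

def _read_keyword(path: Path):
    nodes_raw: list[tuple[int, float, float, float]] = []
    solids: list[list[int]] = []
    shells: list[list[int]] = []
    beams: list[list[int]] = []
    section = None
    label = path.stem
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        s = line.rstrip()
        if not s.strip() or s.lstrip().startswith("$"):
            continue
        if s.startswith("*"):
            upper = s.upper()
            if upper.startswith("*NODE"):
                section = "node"
            elif upper.startswith("*ELEMENT_SOLID"):
                section = "solid"
            elif upper.startswith("*ELEMENT_SHELL"):
                section = "shell"
            elif upper.startswith("*ELEMENT_BEAM"):
                section = "beam"
            elif upper.startswith("*END"):
                break
            else:
                section = None  # *PART, *KEYWORD, material cards... ignored
            continue
        parts = s.replace(",", " ").split()
        try:
            if section == "node":
                nodes_raw.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
            elif section == "solid":
                solids.append([int(p) for p in parts])
            elif section == "shell":
                shells.append([int(p) for p in parts])
            elif section == "beam":
                beams.append([int(p) for p in parts])
        except (ValueError, IndexError):
            raise MeshParseError(f"{path}:{ln}: malformed data line {s!r}")
    if solids:
        # eid pid n1..n8; tetra written with n4 repeated into n5..n8
        conn = []
        kind = None
        for row in solids:
            body = row[2:]
            if len(body) >= 8 and len(set(body[3:8])) == 1 and body[3] == body[4]:
                cell, k = body[:4], "tet"
            elif len(body) == 4:
                cell, k = body, "tet"
            elif len(body) >= 8:
                cell, k = body[:8], "hex"
            else:
                raise UnsupportedElementError(f"{path}: solid card with {len(body)} nodes")
            if kind is not None and k != kind:
                raise UnsupportedElementError(f"{path}: mixed solid families")
            kind = k
            conn.append(cell)
        conn_rows = [[0] + c for c in conn]  # _assemble drops leading id
        return _assemble_id_based(nodes_raw, conn_rows, kind, label, path)
    if shells:
        conn = []
        kind = None
        for row in shells:
            body = row[2:]
            if len(body) >= 4 and body[2] != body[3]:
                cell, k = body[:4], "quad"
            else:
                cell, k = body[:3], "tri"
            if kind is not None and k != kind:
                raise UnsupportedElementError(f"{path}: mixed shell families")
            kind = k
            conn.append(cell)
        conn_rows = [[0] + c for c in conn]
        return _assemble_id_based(nodes_raw, conn_rows, kind, label, path)
    raise MeshParseError(f"{path}: no solid or shell elements found")


def _write_keyword(mesh, path: Path, *, part_id: int = 1,
                   metadata_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("*KEYWORD\n")
        fh.write(f"$ {mesh.part_label or 'tethex mesh'}\n")
        for line in metadata_comments:
            fh.write(f"$ {line}\n")
        fh.write("*PART\n")
        fh.write(f"$ {mesh.part_label or 'part'}\n")
        fh.write(f"{part_id:10d}\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, 1):
            fh.write(f"{i:8d} {x:.9g} {y:.9g} {z:.9g}\n")
        if isinstance(mesh, (TetMesh, HexMesh)):
            fh.write("*ELEMENT_SOLID\n")
            for e, row in enumerate(mesh.elements + 1, 1):
                cells = list(row)
                if len(cells) == 4:
                    cells = cells + [cells[3]] * 4
                fh.write(f"{e:8d}{part_id:8d}" + "".join(f"{n:8d}" for n in cells) + "\n")
        elif isinstance(mesh, SurfaceMesh):
            fh.write("*ELEMENT_SHELL\n")
            for e, row in enumerate(mesh.elements + 1, 1):
                cells = list(row)
                if len(cells) == 3:
                    cells = cells + [cells[2]]
                fh.write(f"{e:8d}{part_id:8d}" + "".join(f"{n:8d}" for n in cells) + "\n")
        else:
            raise TypeError(f"cannot write {type(mesh).__name__} to keyword")
        fh.write("*END\n")
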