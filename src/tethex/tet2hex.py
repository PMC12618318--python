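"""Tetrahedral-to-hexahedral mesh conversion.

Each 4-node tetrahedron is cut into four 8-node hexahedra by inserting the
six edge midpoints, the four face centroids and the element centroid, and
connecting them.  Every triangular face of the input mesh is thereby split
into three quadrilaterals (vertex - edge midpoint - face centroid - other
edge midpoint), so the converted mesh remains conformal across shared faces
and its boundary carries exactly three quads per input boundary triangle.

For an equilateral triangular face the three quads each have interior angles
of 120 deg (at the centroid), 90 deg (at the midpoints) and 60 deg (at the
vertex).  As the input triangle degrades, quad corners open up; a constraint
pass therefore relaxes the inserted nodes until every hexahedral face-corner
angle falls below a configurable bound (140 deg by default) or the iteration
budget is exhausted, and any residual violators are flagged — never deleted.

The four hexahedra partition the tetrahedron exactly, so total volume is
conserved to round-off before smoothing; the smoothing volume drift is
reported in the conversion statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import (
    HEX_FACES,
    TET_EDGES,
    TET_FACES,
    HexMesh,
    MeshError,
    SurfaceMesh,
    TetMesh,
)

__all__ = [
    "ConversionConfig",
    "ConversionResult",
    "convert_tet_to_hex",
    "enforce_angle_constraint",
    "subdivide_triangle",
    "predict_quad_angles",
    "hex_face_corner_angles",
    "max_face_corner_angle",
]

# vertex orderings (a, b, c, d), one per tet corner, all even permutations of
# (0,1,2,3): the hex grown at vertex a is (Va, Mab, Fabc, Mac | Mad, Fabd, C,
# Facd) and inherits a positive corner Jacobian from a positive tet.
_CORNER_ORDER = np.array([[0, 1, 2, 3], [1, 0, 3, 2], [2, 3, 0, 1], [3, 2, 1, 0]])

_DEGENERATE_VOLUME = 1e-12  # mm^3, below coordinate round-trip precision


@dataclass
class ConversionConfig:
    """Knobs of the conversion.

    max_angle_deg
        Upper bound enforced on every hexahedral face-corner angle.
    smoothing_iterations / smoothing_relaxation
        Budget and under-relaxation factor of the constraint pass.
    preserve_boundary
        Keep boundary-surface nodes fixed during smoothing so the converted
        body does not shrink away from its input surface.
    """

    max_angle_deg: float = 140.0
    smoothing_iterations: int = 10
    smoothing_relaxation: float = 0.5
    preserve_boundary: bool = True

    def __post_init__(self):
        if not 0.0 < self.max_angle_deg < 180.0:
            raise ValueError("max_angle_deg must lie in (0, 180)")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")
        if not 0.0 < self.smoothing_relaxation <= 1.0:
            raise ValueError("smoothing_relaxation must lie in (0, 1]")


@dataclass
class ConversionResult:
    hex_mesh: HexMesh
    node_provenance: dict
    boundary_quads: SurfaceMesh
    flagged_elements: np.ndarray
    stats: dict = field(default_factory=dict)


def _angles_at_corners(p0, p1, p2):
    """Angle (deg) at p0 between the rays p0->p1 and p0->p2 (3D, any shape)."""
    u = p1 - p0
    v = p2 - p0
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = np.where(nu * nv == 0.0, 1.0, nu * nv)
    c = np.clip(np.einsum("...i,...i->...", u, v) / denom, -1.0, 1.0)
    return np.degrees(np.arccos(c))


# the 24 face corners of a brick as (corner, next, previous) local indices
_CORNER_TRIPLETS = np.array(
    [(f[k], f[(k + 1) % 4], f[(k - 1) % 4]) for f in HEX_FACES for k in range(4)]
)


def hex_face_corner_angles(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """(n_hex, 6, 4) face-corner angles in degrees.

    Faces may be non-planar, so the angle is measured in 3D between the two
    face edge vectors meeting at each corner.
    """
    p = nodes[hexes]  # (n, 8, 3)
    q = p[:, HEX_FACES]  # (n, 6, 4, 3)
    prev = np.roll(np.arange(4), 1)
    nxt = np.roll(np.arange(4), -1)
    return _angles_at_corners(q, q[:, :, nxt], q[:, :, prev])


def max_face_corner_angle(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Per-element maximum face-corner angle in degrees.

    Loops over the 24 face corners with flat arrays so million-element
    meshes are audited without giant temporaries.
    """
    if len(hexes) == 0:
        return np.zeros(0)
    worst = np.zeros(len(hexes))
    for a, b, c in _CORNER_TRIPLETS:
        p0 = nodes[hexes[:, a]]
        u = nodes[hexes[:, b]] - p0
        v = nodes[hexes[:, c]] - p0
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        denom = np.where(nu * nv == 0.0, 1.0, nu * nv)
        cos = np.clip(np.einsum("ij,ij->i", u, v) / denom, -1.0, 1.0)
        np.maximum(worst, np.arccos(cos), out=worst)
    return np.degrees(worst)


def subdivide_triangle(triangle: np.ndarray):
    """Split one triangle into three quadrilaterals.

    Returns ``(quads, provenance)`` where ``quads`` is a (3, 4, 3) coordinate
    array — quad ``i`` is grown at vertex ``i`` with node cycle (vertex,
    adjacent edge midpoint, face centroid, other adjacent edge midpoint) —
    and ``provenance`` lists the role of each quad corner.  The three quads
    tile the triangle exactly.
    """
    tri = np.asarray(triangle, dtype=float).reshape(3, 3) if np.asarray(triangle).size == 9 \
        else np.asarray(triangle, dtype=float)
    if tri.shape != (3, 3):
        tri = np.column_stack([tri, np.zeros(3)]) if tri.shape == (3, 2) else tri
    if tri.shape != (3, 3):
        raise ValueError("triangle must be three 2- or 3-D points")
    area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area2 < 1e-14:
        raise MeshError("degenerate (collinear) triangle")
    centroid = tri.mean(axis=0)
    mids = {(i, j): (tri[i] + tri[j]) / 2.0 for i, j in ((0, 1), (0, 2), (1, 2))}

    def mid(i, j):
        return mids[(min(i, j), max(i, j))]

    quads = np.empty((3, 4, 3))
    provenance = []
    for v in range(3):
        a, b = [x for x in range(3) if x != v]
        quads[v] = [tri[v], mid(v, a), centroid, mid(v, b)]
        provenance.append(
            [("vertex", v), ("edge_midpoint", (min(v, a), max(v, a))),
             ("face_centroid", (0, 1, 2)), ("edge_midpoint", (min(v, b), max(v, b)))]
        )
    return quads, provenance


def predict_quad_angles(triangle_angles) -> np.ndarray:
    """Interior angles of the three quads produced by subdividing a triangle.

    Input: the triangle's three interior angles in degrees (must sum to
    180).  Output: (3, 4) array of quad angles in the cycle order (vertex,
    midpoint, centroid, midpoint) for the quad grown at each triangle
    vertex.  Used as a pre-conversion screen: a triangle whose predicted
    quads already violate the angle bound will need smoothing or flagging.
    """
    ang = np.asarray(triangle_angles, dtype=float)
    if ang.shape != (3,) or (ang <= 0).any():
        raise ValueError("need three positive angles")
    if not np.isclose(ang.sum(), 180.0, atol=1e-6):
        raise ValueError("triangle angles must sum to 180 degrees")
    # representative triangle: unit base 0-1, vertex 2 placed by law of sines
    a0, a1, a2 = np.radians(ang)
    r0 = np.sin(a1) / np.sin(a2)  # length of side 0-2
    tri = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                    [r0 * np.cos(a0), r0 * np.sin(a0), 0.0]])
    quads, _ = subdivide_triangle(tri)
    prev = np.roll(np.arange(4), 1)
    nxt = np.roll(np.arange(4), -1)
    return _angles_at_corners(quads, quads[:, nxt], quads[:, prev])


def convert_tet_to_hex(mesh: TetMesh, config: ConversionConfig | None = None) -> ConversionResult:
    """Convert a tetrahedral mesh into four hexahedra per tetrahedron.

    Inserted nodes on shared edges and faces are deduplicated through
    canonical (sorted node-id) keys, so adjacent elements stay conformal.
    After construction the angle constraint is enforced (see
    :func:`enforce_angle_constraint`); hexes still violating the bound are
    listed in ``flagged_elements``.

    The output node array is laid out as [input vertices | edge midpoints |
    face centroids | element centroids], which realises the counting identity
    ``n_nodes = V + E + F + T``.
    """
    config = config or ConversionConfig()
    if mesh.n_elements == 0:
        raise MeshError("cannot convert an empty tetrahedral mesh")

    vols = np.einsum(
        "ij,ij->i",
        np.cross(mesh.nodes[mesh.elements[:, 1]] - mesh.nodes[mesh.elements[:, 0]],
                 mesh.nodes[mesh.elements[:, 2]] - mesh.nodes[mesh.elements[:, 0]]),
        mesh.nodes[mesh.elements[:, 3]] - mesh.nodes[mesh.elements[:, 0]],
    ) / 6.0
    bad = np.flatnonzero(np.abs(vols) < _DEGENERATE_VOLUME)
    if bad.size:
        raise MeshError(f"degenerate tetrahedron (|volume| < {_DEGENERATE_VOLUME} mm^3): "
                        f"element {int(bad[0])}")

    import warnings as _warnings

    uniq, inv = np.unique(np.round(mesh.nodes, 9), axis=0, return_inverse=True)
    if len(uniq) != mesh.n_nodes:
        _warnings.warn("input mesh has duplicate nodes at identical coordinates; "
                       "conversion keeps them distinct (non-conformal input)")

    nv = mesh.n_nodes
    tets = mesh.elements

    edges_all = np.sort(tets[:, TET_EDGES].reshape(-1, 2), axis=1)
    edges, edge_inv = np.unique(edges_all, axis=0, return_inverse=True)
    edge_of_tet = edge_inv.reshape(-1, 6)  # local edge order = TET_EDGES

    faces_all = np.sort(tets[:, TET_FACES].reshape(-1, 3), axis=1)
    faces, face_inv, face_counts = np.unique(
        faces_all, axis=0, return_inverse=True, return_counts=True)
    face_of_tet = face_inv.reshape(-1, 4)  # local face order = TET_FACES

    ne, nf, nt = len(edges), len(faces), len(tets)
    nodes = np.concatenate([
        mesh.nodes,
        mesh.nodes[edges].mean(axis=1),
        mesh.nodes[faces].mean(axis=1),
        mesh.nodes[tets].mean(axis=1),
    ])
    e_off, f_off, t_off = nv, nv + ne, nv + ne + nf

    # lookup tables: midpoint node of edge (a,b) and centroid node of the
    # face opposite nothing in particular — keyed by local vertex sets
    edge_local = {tuple(sorted(e)): k for k, e in enumerate(TET_EDGES)}
    # local face index containing vertices {a,b,c}
    face_local = {tuple(sorted(f)): k for k, f in enumerate(TET_FACES)}

    hexes = np.empty((4 * nt, 8), dtype=np.int64)
    for corner, (a, b, c, d) in enumerate(_CORNER_ORDER):
        mab = e_off + edge_of_tet[:, edge_local[tuple(sorted((a, b)))]]
        mac = e_off + edge_of_tet[:, edge_local[tuple(sorted((a, c)))]]
        mad = e_off + edge_of_tet[:, edge_local[tuple(sorted((a, d)))]]
        fabc = f_off + face_of_tet[:, face_local[tuple(sorted((a, b, c)))]]
        fabd = f_off + face_of_tet[:, face_local[tuple(sorted((a, b, d)))]]
        facd = f_off + face_of_tet[:, face_local[tuple(sorted((a, c, d)))]]
        cent = t_off + np.arange(nt)
        hexes[corner::4] = np.column_stack(
            [tets[:, a], mab, fabc, mac, mad, fabd, cent, facd]
        )
    # hexes[corner::4] above already interleaves: tet order, corner sub-order
    provenance = {}
    for k in range(nv):
        provenance[k] = ("vertex", int(mesh.node_ids[k]) if mesh.node_ids is not None else k)
    for k, (i, j) in enumerate(edges):
        provenance[e_off + k] = ("edge_midpoint", (int(i), int(j)))
    for k, f in enumerate(faces):
        provenance[f_off + k] = ("face_centroid", tuple(int(x) for x in f))
    for k in range(nt):
        provenance[t_off + k] = ("element_centroid", k)

    hex_mesh = HexMesh(nodes, hexes, part_label=mesh.part_label)

    # boundary quads directly from the input boundary triangles: each
    # outward-oriented boundary face (i, j, k) yields the three quads
    # (i, m_ij, f, m_ik), (j, m_jk, f, m_ij), (k, m_ik, f, m_jk), which
    # keeps the 3-quads-per-triangle identity and outward orientation
    bquads = []
    on_boundary = (face_counts[face_inv] == 1).reshape(-1, 4)
    for lf in range(4):
        els = np.flatnonzero(on_boundary[:, lf])
        if not els.size:
            continue
        li, lj, lk = TET_FACES[lf]
        gi, gj, gk = tets[els, li], tets[els, lj], tets[els, lk]
        fc = f_off + face_of_tet[els, lf]
        mij = e_off + edge_of_tet[els][:, edge_local[tuple(sorted((li, lj)))]]
        mjk = e_off + edge_of_tet[els][:, edge_local[tuple(sorted((lj, lk)))]]
        mik = e_off + edge_of_tet[els][:, edge_local[tuple(sorted((li, lk)))]]
        bquads.append(np.column_stack([gi, mij, fc, mik]))
        bquads.append(np.column_stack([gj, mjk, fc, mij]))
        bquads.append(np.column_stack([gk, mik, fc, mjk]))
    bquad_arr = (np.concatenate(bquads) if bquads
                 else np.zeros((0, 4), dtype=np.int64))
    bsurf = SurfaceMesh(nodes, bquad_arr, part_label=mesh.part_label)
    result = ConversionResult(
        hex_mesh=hex_mesh,
        node_provenance=provenance,
        boundary_quads=bsurf,
        flagged_elements=np.zeros(0, dtype=np.int64),
        stats={
            "input_tets": nt,
            "output_hexes": 4 * nt,
            "inserted_nodes": {"edge_midpoint": ne, "face_centroid": nf,
                               "element_centroid": nt},
            "input_volume": float(np.abs(vols).sum()),
            "smoothing_iterations_used": 0,
        },
    )
    return enforce_angle_constraint(result, config)


# angles are driven below the bound by this safety margin so the stationary
# state of the descent sits clear of the flag threshold
_ANGLE_MARGIN_DEG = 5.0


def _boundary_constraints(nodes: np.ndarray, quads: np.ndarray, n: int):
    """Per-boundary-node movement restriction that preserves the surface.

    A boundary node whose incident boundary quads are coplanar may slide in
    that plane; a node on the crease between exactly two planes may slide
    along the crease line; anything else is pinned.  Returns
    ``(kind, direction)``: kind 0 = interior (free), 1 = in-plane (direction
    = plane normal), 2 = on-line (direction = line direction), 3 = fixed.
    """
    kind = np.zeros(n, dtype=np.int8)
    direction = np.zeros((n, 3))
    q = nodes[quads]
    normals = np.cross(q[:, 1] - q[:, 0], q[:, 2] - q[:, 0])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    incident: dict[int, list[int]] = {}
    for qi, quad in enumerate(quads):
        for node in quad:
            incident.setdefault(int(node), []).append(qi)
    for node, qids in incident.items():
        ns = normals[qids]
        ns = ns * np.where(ns @ ns[0] < 0, -1.0, 1.0)[:, None]  # hemisphere
        uniq = np.unique(np.round(ns, 6), axis=0)
        if len(uniq) == 1:
            kind[node] = 1
            direction[node] = uniq[0]
        elif len(uniq) == 2:
            line = np.cross(uniq[0], uniq[1])
            nrm = np.linalg.norm(line)
            if nrm > 1e-9:
                kind[node] = 2
                direction[node] = line / nrm
            else:
                kind[node] = 1
                direction[node] = uniq[0]
        else:
            kind[node] = 3
    return kind, direction


def enforce_angle_constraint(result: ConversionResult, config: ConversionConfig | None = None) -> ConversionResult:
    """Drive hexahedral face-corner angles below the bound by moving
    inserted nodes.

    Each iteration evaluates every face-corner angle and descends the
    gradient of the quadratic penalty ``sum (theta - theta_target)^2`` over
    corners exceeding ``max_angle_deg`` minus a small margin; the step is
    ``smoothing_relaxation`` times the local edge length squared, capped at
    a quarter edge length so elements cannot be pushed through themselves.
    Original tet vertices never move.  With ``preserve_boundary`` on,
    boundary nodes move only tangentially within planar boundary patches
    (or along crease lines), which keeps the boundary geometry exact; nodes
    on genuinely curved corners stay pinned.  Iteration stops when every
    angle is within ``max_angle_deg`` or the budget runs out; residual
    violators are flagged, never removed.  Volume drift is recorded in
    ``stats['volume_drift_rel']``.
    """
    config = config or ConversionConfig()
    mesh = result.hex_mesh
    nodes = mesh.nodes.copy()
    hexes = mesh.elements
    n = len(nodes)

    movable = np.zeros(n, dtype=bool)
    for nid, (kind, _) in result.node_provenance.items():
        if kind != "vertex":
            movable[nid] = True

    ckind = np.zeros(n, dtype=np.int8)
    cdir = np.zeros((n, 3))
    if config.preserve_boundary and len(result.boundary_quads.faces):
        ckind, cdir = _boundary_constraints(nodes, result.boundary_quads.faces, n)
        movable &= ckind != 3

    from .mesh_core import HEX_EDGES, _hex_signed_volumes

    # local length scale: mean incident hex-edge length per node
    epairs = hexes[:, HEX_EDGES].reshape(-1, 2)
    elen = np.linalg.norm(nodes[epairs[:, 0]] - nodes[epairs[:, 1]], axis=1)
    cnt = (np.bincount(epairs[:, 0], minlength=n)
           + np.bincount(epairs[:, 1], minlength=n)).astype(float)
    h = (np.bincount(epairs[:, 0], weights=elen, minlength=n)
         + np.bincount(epairs[:, 1], weights=elen, minlength=n)) / np.maximum(cnt, 1.0)
    h[cnt == 0] = 1.0

    theta_max = np.radians(config.max_angle_deg)
    theta_tgt = np.radians(max(config.max_angle_deg - _ANGLE_MARGIN_DEG, 1.0))

    def _penalty_pass(pos, with_grad=True):
        """Worst angle, total penalty and (optionally) its averaged gradient."""
        grad = np.zeros((n, 3)) if with_grad else None
        count = np.zeros(n) if with_grad else None
        worst = 0.0
        energy = 0.0
        for a, b, c in _CORNER_TRIPLETS:
            i0, i1, i2 = hexes[:, a], hexes[:, b], hexes[:, c]
            u = pos[i1] - pos[i0]
            v = pos[i2] - pos[i0]
            lu = np.linalg.norm(u, axis=1)
            lv = np.linalg.norm(v, axis=1)
            uh = u / np.maximum(lu, 1e-300)[:, None]
            vh = v / np.maximum(lv, 1e-300)[:, None]
            cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            theta = np.arccos(cos)
            worst = max(worst, float(theta.max()))
            excess = theta - theta_tgt
            active = excess > 0
            if not active.any():
                continue
            idx = np.flatnonzero(active)
            energy += float((excess[idx] ** 2).sum())
            if not with_grad:
                continue
            sin = np.maximum(np.sqrt(1.0 - cos[idx] ** 2), 1e-9)
            coef = 2.0 * excess[idx]
            g1 = -(vh[idx] - cos[idx, None] * uh[idx]) / (lu[idx] * sin)[:, None]
            g2 = -(uh[idx] - cos[idx, None] * vh[idx]) / (lv[idx] * sin)[:, None]
            g0 = -(g1 + g2)
            for gi, ii in ((g0, i0[idx]), (g1, i1[idx]), (g2, i2[idx])):
                w = coef[:, None] * gi
                for k in range(3):
                    grad[:, k] += np.bincount(ii, weights=w[:, k], minlength=n)
                count += np.bincount(ii, minlength=n)
        if with_grad:
            grad /= np.maximum(count, 1.0)[:, None]
        return worst, energy, grad

    def _project(disp):
        plane = ckind == 1
        disp[plane] -= np.einsum("ij,ij->i", disp[plane], cdir[plane])[:, None] * cdir[plane]
        line = ckind == 2
        disp[line] = np.einsum("ij,ij->i", disp[line], cdir[line])[:, None] * cdir[line]
        mag = np.linalg.norm(disp, axis=1)
        cap = 0.2 * h
        over = mag > cap
        disp[over] *= (cap[over] / mag[over])[:, None]
        return disp

    vol0 = _hex_signed_volumes(nodes, hexes).sum()
    iters_used = 0
    scale = config.smoothing_relaxation
    for it in range(config.smoothing_iterations):
        worst, energy, grad = _penalty_pass(nodes)
        if worst <= theta_max + 1e-12:
            break
        iters_used = it + 1
        accepted = False
        for _ in range(4):  # backtracking on the penalty energy
            disp = _project(-scale * (h**2)[:, None] * grad)
            trial = nodes.copy()
            trial[movable] += disp[movable]
            _, e_new, _ = _penalty_pass(trial, with_grad=False)
            if e_new < energy:
                nodes = trial
                accepted = True
                scale = min(scale * 1.2, config.smoothing_relaxation)
                break
            scale *= 0.5
        if not accepted:
            break  # stationary for this penalty; residuals get flagged

    angles = max_face_corner_angle(nodes, hexes)
    flagged = np.flatnonzero(angles > config.max_angle_deg + 1e-9)
    vol1 = _hex_signed_volumes(nodes, hexes).sum()

    stats = dict(result.stats)
    stats["smoothing_iterations_used"] = iters_used
    stats["max_face_corner_angle_deg"] = float(angles.max()) if len(angles) else 0.0
    stats["flagged"] = int(flagged.size)
    stats["volume_drift_rel"] = float(abs(vol1 - vol0) / abs(vol0)) if vol0 else 0.0
    stats["output_volume"] = float(vol1)

    new_mesh = HexMesh(nodes, hexes, part_label=mesh.part_label)
    return ConversionResult(
        hex_mesh=new_mesh,
        node_provenance=result.node_provenance,
        boundary_quads=SurfaceMesh(nodes, result.boundary_quads.faces,
                                   part_label=result.boundary_quads.part_label),
        flagged_elements=flagged,
        stats=stats,
    )
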