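"""Element-quality metrics and mesh quality reports.

The metrics follow the standard textbook definitions used by FE preprocessor
quality panels:

scaled Jacobian
    Hexahedra: at each of the 8 corners, the determinant of the three unit
    edge vectors leaving that corner (right-handed corner triple); the
    element value is the minimum over corners.  1 for an orthogonal corner
    frame, 0 for a flattened element, negative when inverted.  Tetrahedra:
    the corner determinant of unit edge vectors scaled by sqrt(2) so the
    regular tetrahedron scores 1, minimum over the 4 corners.
aspect ratio
    Longest over shortest element edge (>= 1).
skewness (deg)
    Maximum deviation of any face-corner angle from the ideal angle (60 deg
    for triangular faces, 90 deg for quadrilateral faces).
warping (deg)
    For quadrilateral faces: split the quad along each diagonal and measure
    the angle between the two triangle normals; take the worse diagonal,
    then the worst face.  0 for planar faces.
maximum angle (deg)
    Largest face-corner angle of the element.

The report mirrors the usual mesh-statistics table: element count, average
mesh size (mean +/- SD of all element edge lengths, mm), minimum Jacobian
and the percentage of elements whose aspect ratio is below a report cutoff
(3 by default).  Acceptance thresholds default to aspect ratio 4, skewness
45 deg, warping 20 deg, maximum angle 140 deg, and minimum scaled Jacobian
0.4 for hexahedra / 0.8 for tetrahedra.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .mesh_core import (
    HEX_CORNER_NEIGHBORS,
    HEX_EDGES,
    HEX_FACES,
    HexMesh,
    SurfaceMesh,
    TET_EDGES,
    TET_FACES,
    TetMesh,
)
from .tet2hex import _angles_at_corners

__all__ = [
    "QualityThresholds",
    "QualityReport",
    "scaled_jacobian",
    "aspect_ratio",
    "skewness_deg",
    "warping_deg",
    "max_corner_angle_deg",
    "average_mesh_size",
    "quality_report",
]

_ASPECT_CAP = 1e6  # sentinel for degenerate (zero-edge) elements


@dataclass
class QualityThresholds:
    aspect_ratio_max: float = 4.0
    skewness_max_deg: float = 45.0
    warping_max_deg: float = 20.0
    max_angle_deg: float = 140.0
    jacobian_min_hex: float = 0.4
    jacobian_min_tet: float = 0.8
    aspect_report_cutoff: float = 3.0

    def __post_init__(self):
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all thresholds must be positive")
        if self.max_angle_deg >= 180 or self.skewness_max_deg >= 180:
            raise ValueError("angle thresholds must be < 180 degrees")


@dataclass
class QualityReport:
    records: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _coerce_batch(element: np.ndarray) -> tuple[np.ndarray, str]:
    """Accept one element or a batch; return ((n, k, 3) coords, family)."""
    arr = np.asarray(element, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("element must be (k, 3) or (n, k, 3) coordinates")
    k = arr.shape[1]
    if k == 4:
        return arr, "tet"
    if k == 8:
        return arr, "hex"
    raise ValueError(f"unsupported element with {k} corners")


def _edges_of(arr: np.ndarray, family: str) -> np.ndarray:
    table = TET_EDGES if family == "tet" else HEX_EDGES
    e = arr[:, table]
    return np.linalg.norm(e[:, :, 1] - e[:, :, 0], axis=-1)


def scaled_jacobian(element) -> np.ndarray | float:
    """Minimum corner scaled Jacobian of a tet or hex (batch-aware).

    Degenerate corners (coincident nodes) score 0.
    """
    arr, family = _coerce_batch(element)
    if family == "hex":
        dets = np.empty((len(arr), 8))
        for c in range(8):
            n1, n2, n3 = HEX_CORNER_NEIGHBORS[c]
            u = arr[:, n1] - arr[:, c]
            v = arr[:, n2] - arr[:, c]
            w = arr[:, n3] - arr[:, c]
            lu = np.linalg.norm(u, axis=1)
            lv = np.linalg.norm(v, axis=1)
            lw = np.linalg.norm(w, axis=1)
            denom = lu * lv * lw
            det = np.einsum("ij,ij->i", np.cross(u, v), w)
            dets[:, c] = np.where(denom > 0, det / np.where(denom == 0, 1, denom), 0.0)
        out = dets.min(axis=1)
    else:
        dets = np.empty((len(arr), 4))
        for c in range(4):
            others = [i for i in range(4) if i != c]
            u = arr[:, others[0]] - arr[:, c]
            v = arr[:, others[1]] - arr[:, c]
            w = arr[:, others[2]] - arr[:, c]
            lu = np.linalg.norm(u, axis=1)
            lv = np.linalg.norm(v, axis=1)
            lw = np.linalg.norm(w, axis=1)
            denom = lu * lv * lw
            det = np.abs(np.einsum("ij,ij->i", np.cross(u, v), w))
            dets[:, c] = np.where(denom > 0, np.sqrt(2.0) * det / np.where(denom == 0, 1, denom), 0.0)
        out = dets.min(axis=1)
    return out if out.size > 1 else float(out[0])


def aspect_ratio(element) -> np.ndarray | float:
    """Longest / shortest edge; degenerate elements get a capped sentinel."""
    arr, family = _coerce_batch(element)
    lengths = _edges_of(arr, family)
    lo = lengths.min(axis=1)
    hi = lengths.max(axis=1)
    out = np.where(lo > 0, hi / np.where(lo == 0, 1, lo), _ASPECT_CAP)
    return out if out.size > 1 else float(out[0])


def _face_corner_angles(arr: np.ndarray, family: str) -> np.ndarray:
    """(n, faces, corners) corner angles in degrees."""
    if family == "hex":
        return _hex_angles(arr)
    q = arr[:, TET_FACES]  # (n, 4, 3, 3)
    nxt = np.roll(np.arange(3), -1)
    prev = np.roll(np.arange(3), 1)
    return _angles_at_corners(q, q[:, :, nxt], q[:, :, prev])


def _hex_angles(arr: np.ndarray) -> np.ndarray:
    q = arr[:, HEX_FACES]
    nxt = np.roll(np.arange(4), -1)
    prev = np.roll(np.arange(4), 1)
    return _angles_at_corners(q, q[:, :, nxt], q[:, :, prev])


def skewness_deg(element) -> np.ndarray | float:
    """Max deviation of face-corner angles from the ideal (60 tri / 90 quad)."""
    arr, family = _coerce_batch(element)
    ideal = 60.0 if family == "tet" else 90.0
    ang = _face_corner_angles(arr, family)
    out = np.abs(ang - ideal).max(axis=(1, 2))
    return out if out.size > 1 else float(out[0])


def warping_deg(quad_face) -> np.ndarray | float:
    """Warping of one or more quad faces: angle between the normals of the
    two triangles obtained by cutting along a diagonal, max over diagonals.
    """
    q = np.asarray(quad_face, dtype=float)
    if q.ndim == 2:
        q = q[None]
    if q.shape[1:] != (4, 3):
        raise ValueError("quad face must be (4, 3) or (n, 4, 3)")
    out = np.zeros(len(q))
    for d in ((0, 2), (1, 3)):
        i, j = d
        k, l = [x for x in range(4) if x not in d]
        n1 = np.cross(q[:, j] - q[:, i], q[:, k] - q[:, i])
        n2 = np.cross(q[:, l] - q[:, i], q[:, j] - q[:, i])
        l1 = np.linalg.norm(n1, axis=1)
        l2 = np.linalg.norm(n2, axis=1)
        denom = np.where(l1 * l2 == 0, 1.0, l1 * l2)
        c = np.clip(np.einsum("ij,ij->i", n1, n2) / denom, -1.0, 1.0)
        out = np.maximum(out, np.degrees(np.arccos(c)))
    return out if out.size > 1 else float(out[0])


def _hex_warping(arr: np.ndarray) -> np.ndarray:
    faces = arr[:, HEX_FACES].reshape(-1, 4, 3)
    w = np.asarray(warping_deg(faces)).reshape(len(arr), 6)
    return w.max(axis=1)


def max_corner_angle_deg(element) -> np.ndarray | float:
    """Largest face-corner angle of a tet or hex, in degrees."""
    arr, family = _coerce_batch(element)
    out = _face_corner_angles(arr, family).max(axis=(1, 2))
    return out if out.size > 1 else float(out[0])


def average_mesh_size(mesh: TetMesh | HexMesh | SurfaceMesh) -> tuple[float, float]:
    """Mean and SD (mm) of all element edge lengths (population SD)."""
    if isinstance(mesh, TetMesh):
        table = TET_EDGES
    elif isinstance(mesh, HexMesh):
        table = HEX_EDGES
    elif isinstance(mesh, SurfaceMesh):
        k = mesh.faces.shape[1]
        table = np.column_stack([np.arange(k), np.roll(np.arange(k), -1)])
    else:
        raise TypeError("unsupported mesh type")
    e = mesh.nodes[mesh.elements[:, table]]
    lengths = np.linalg.norm(e[:, :, 1] - e[:, :, 0], axis=-1).ravel()
    return float(lengths.mean()), float(lengths.std())


def quality_report(mesh: TetMesh | HexMesh, thresholds: QualityThresholds | None = None) -> QualityReport:
    """Per-element metric table plus summary statistics.

    The summary is recomputable from the records: element count, mean +/- SD
    mesh size, min scaled Jacobian, % of elements with aspect ratio below the
    report cutoff, and pass rates for each threshold.
    """
    thr = thresholds or QualityThresholds()
    if isinstance(mesh, TetMesh):
        family, jmin = "tet", thr.jacobian_min_tet
    elif isinstance(mesh, HexMesh):
        family, jmin = "hex", thr.jacobian_min_hex
    else:
        raise TypeError("quality_report expects a TetMesh or HexMesh")
    arr = mesh.element_coords()
    sj = np.atleast_1d(scaled_jacobian(arr))
    ar = np.atleast_1d(aspect_ratio(arr))
    sk = np.atleast_1d(skewness_deg(arr))
    ma = np.atleast_1d(max_corner_angle_deg(arr))
    wp = _hex_warping(arr) if family == "hex" else np.zeros(len(arr))

    records = pd.DataFrame({
        "element_id": np.arange(len(arr)),
        "scaled_jacobian": sj,
        "aspect_ratio": ar,
        "skewness_deg": sk,
        "warping_deg": wp,
        "max_angle_deg": ma,
        "pass_jacobian": sj >= jmin,
        "pass_aspect": ar <= thr.aspect_ratio_max,
        "pass_skewness": sk <= thr.skewness_max_deg,
        "pass_warping": wp <= thr.warping_max_deg,
        "pass_max_angle": ma <= thr.max_angle_deg,
    })
    mean_size, sd_size = average_mesh_size(mesh)
    summary = {
        "element_type": "3D Hexahedral" if family == "hex" else "3D Tetrahedral",
        "n_elements": int(len(arr)),
        "mesh_size_mean_mm": mean_size,
        "mesh_size_sd_mm": sd_size,
        "min_jacobian": float(sj.min()),
        "pct_aspect_below_cutoff": float(100.0 * np.mean(ar < thr.aspect_report_cutoff)),
        "pct_pass_jacobian": float(100.0 * records["pass_jacobian"].mean()),
        "pct_pass_max_angle": float(100.0 * records["pass_max_angle"].mean()),
        "n_above_max_angle": int((~records["pass_max_angle"]).sum()),
    }
    return QualityReport(records=records, summary=summary)
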