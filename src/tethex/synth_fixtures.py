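"""Deterministic generators for every input the toolkit's tests need.

Volume meshes come from a cubic lattice in which each cell is cut into six
tetrahedra around its main diagonal (the Kuhn/Freudenthal template).  Because
every cell uses the same diagonal the lattice is conformal: tetrahedra in
neighbouring cells share whole faces and node ids.  The staircase boundary
is a deliberate trade-off — no external mesher, bit-reproducible output —
and is adequate for exercising conversion, quality and volume code; it is
not an anatomical brain surface.

The parametric vertebra is a box-like body plus a spinous process bar whose
six landmark points are constructed directly from the requested dimensions,
so every morphometric measure has an exact ground truth.  Time-series
fixtures are seeded damped oscillations standing in for displacement and
flexion-angle curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TetMesh
from .morphometry import TimeSeries, VertebralLandmarks

__all__ = [
    "FixtureSpec",
    "sphere_tet_mesh",
    "two_layer_tet_mesh",
    "parametric_vertebra",
    "damped_oscillation",
    "strain_field",
]

# six tets around the main diagonal (0,0,0)-(1,1,1) of the unit cube;
# corner indices into the 8 cube corners in (x + 2y + 4z) bit order
_CUBE_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]]
)
_KUHN_TETS = np.array(
    [[0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7],
     [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7]]
)


@dataclass
class FixtureSpec:
    """Serializable description of one fixture (kind + parameters + seed)."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = ("sphere_tet", "two_layer_tet", "box_lattice", "parametric_vertebra",
              "damped_oscillation", "strain_field")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")

    def build(self):
        p = dict(self.parameters)
        if self.kind == "sphere_tet":
            return sphere_tet_mesh(**p)
        if self.kind == "two_layer_tet":
            return two_layer_tet_mesh(**p)
        if self.kind == "box_lattice":
            return box_lattice_tet_mesh(**p)
        if self.kind == "parametric_vertebra":
            return parametric_vertebra(**p)
        if self.kind == "damped_oscillation":
            return damped_oscillation(seed=self.seed, **p)
        return None


def _lattice_tets(n_cells: np.ndarray, origin: np.ndarray, cell_edge: float):
    """All nodes and 6-per-cell tets of an (nx, ny, nz) cell lattice."""
    nx, ny, nz = (int(v) for v in n_cells)
    gx, gy, gz = nx + 1, ny + 1, nz + 1
    ii, jj, kk = np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")
    nodes = origin + cell_edge * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)

    def nid(i, j, k):
        return (i * gy + j) * gz + k

    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corner_ids = np.stack(
        [nid(ci + dx, cj + dy, ck + dz) for dx, dy, dz in _CUBE_CORNERS], axis=1
    )  # (ncell, 8)
    tets = corner_ids[:, _KUHN_TETS].reshape(-1, 4)
    return nodes, tets


def box_lattice_tet_mesh(size=(10.0, 10.0, 10.0), cell_edge: float = 1.0,
                         part_label: str = "box") -> TetMesh:
    """Rectangular box, six conformal tets per lattice cell."""
    size = np.asarray(size, dtype=float)
    n_cells = np.maximum(np.round(size / cell_edge).astype(int), 1)
    nodes, tets = _lattice_tets(n_cells, np.zeros(3), cell_edge)
    return _compact(nodes, tets, part_label)


def _compact(nodes, tets, label):
    used, inv = np.unique(tets, return_inverse=True)
    return TetMesh(nodes[used], inv.reshape(-1, 4), part_label=label)


def sphere_tet_mesh(radius: float = 10.0, cell_edge: float = 1.0,
                    part_label: str = "sphere") -> TetMesh:
    """Lattice sphere: keep the tets whose centroid lies inside the sphere.

    Conformal and positively oriented by construction; the surface is a
    lattice staircase, so the volume converges to the analytic sphere volume
    only as ``cell_edge`` shrinks.
    """
    if not 0 < cell_edge < radius:
        raise ValueError("need 0 < cell_edge < radius")
    n = int(np.ceil(radius / cell_edge)) + 1
    origin = -cell_edge * n * np.ones(3)
    nodes, tets = _lattice_tets(np.array([2 * n, 2 * n, 2 * n]), origin, cell_edge)
    centroids = nodes[tets].mean(axis=1)
    keep = np.linalg.norm(centroids, axis=1) < radius
    if not keep.any():
        raise ValueError("no tetrahedron centroid falls inside the sphere; "
                         "decrease cell_edge")
    return _compact(nodes, tets[keep], part_label)


def two_layer_tet_mesh(inner_radius: float = 8.0, outer_radius: float = 10.0,
                       cell_edge: float = 1.0):
    """Concentric two-material ball: inner 'brain' core and 'csf' shell.

    One lattice, labelled by centroid radius, so the material interface is
    conformal (shared faces share node ids).  Returns ``(inner, shell,
    labels)`` where ``labels`` maps each element of the combined mesh.
    """
    import warnings

    if not inner_radius < outer_radius:
        raise ValueError("need inner_radius < outer_radius")
    if outer_radius - inner_radius < cell_edge:
        warnings.warn("shell thinner than one cell: it may be empty in places")
    whole = sphere_tet_mesh(outer_radius, cell_edge, part_label="two_layer")
    centroids = whole.nodes[whole.elements].mean(axis=1)
    r = np.linalg.norm(centroids, axis=1)
    labels = np.where(r < inner_radius, "brain", "csf")
    inner = TetMesh(whole.nodes, whole.elements[labels == "brain"], part_label="brain")
    shell = TetMesh(whole.nodes, whole.elements[labels == "csf"], part_label="csf")
    return whole, inner, shell, labels


def parametric_vertebra(height_ant: float = 12.0, height_post: float = 14.0,
                        depth_sup: float = 15.0, depth_inf: float = 16.0,
                        spinous_len: float = 20.0, body_to_spinous: float = 30.0,
                        rotation=None, translation=None, seed: int | None = None,
                        n_cloud: int = 200):
    """Box-like vertebra with exact ground-truth landmarks.

    The mid-sagittal body corners are built in the y=0 plane (x anterior,
    z superior) so that the generating parameters are recovered exactly:
    vertebral height = (height_ant + height_post)/2, depth =
    (depth_sup + depth_inf)/2, spinous and body-to-spinous lengths as given.
    A surrounding point cloud (body box corners plus seeded surface points,
    distinct extents along x > z > y) is returned for PCA-based
    re-orientation tests.  ``rotation`` (3x3) and ``translation`` pose the
    whole construct rigidly; with ``seed`` the cloud is reproducible.

    Returns ``(cloud, landmarks, true_measures)``.
    """
    for v in (height_ant, height_post, depth_sup, depth_inf, spinous_len, body_to_spinous):
        if v <= 0:
            raise ValueError("all dimensions must be positive")
    # mid-sagittal quadrilateral with the four requested side lengths:
    # posterior edge vertical (length height_post), inferior edge horizontal
    # (length depth_inf); the anterior-superior corner solves
    # |as - ai| = height_ant and |as - ps| = depth_sup in closed form
    A = depth_inf**2 + height_ant**2 + height_post**2 - depth_sup**2
    qa = 4.0 * (depth_inf**2 + height_post**2)
    qb = 4.0 * A * depth_inf
    qc = A**2 - 4.0 * height_post**2 * height_ant**2
    disc = qb**2 - 4.0 * qa * qc
    if disc < 0:
        raise ValueError("requested vertebral dimensions are not realizable "
                         "as a planar quadrilateral")
    t = (-qb + np.sqrt(disc)) / (2.0 * qa)  # root with the taller anterior edge
    z = np.sqrt(max(height_ant**2 - t**2, 0.0))
    post_inf = np.array([0.0, 0.0, 0.0])
    post_sup = np.array([0.0, 0.0, height_post])
    ant_inf = np.array([depth_inf, 0.0, 0.0])
    ant_sup = np.array([depth_inf + t, 0.0, z])
    posterior_mid = (post_inf + post_sup) / 2.0
    spin_distal = posterior_mid - np.array([body_to_spinous, 0.0, 0.0])
    spin_proximal = spin_distal + np.array([spinous_len * np.cos(np.radians(10.0)),
                                            0.0, spinous_len * np.sin(np.radians(10.0))])

    rng = np.random.default_rng(0 if seed is None else seed)
    # lateral half-width kept small so the cloud's principal variances are
    # cleanly ordered x (body+spinous span) > z (height) > y (lateral)
    width_y = 0.18 * min(depth_sup, depth_inf)
    # deterministic box-corner scaffold guaranteeing x > z > y variance order
    depth_mean = (depth_sup + depth_inf) / 2.0
    xs = np.linspace(-body_to_spinous, depth_mean, 9)
    zs = np.linspace(0.0, height_post, 5)
    ys = np.array([-width_y, 0.0, width_y])
    grid = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    jitter = rng.normal(scale=0.05, size=grid.shape)
    cloud = np.vstack([grid + jitter,
                       [post_inf, post_sup, ant_inf, ant_sup, spin_distal, spin_proximal]])

    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    tvec = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    pose = lambda p: p @ R.T + tvec  # noqa: E731

    lm = VertebralLandmarks(
        anterior_superior=pose(ant_sup), anterior_inferior=pose(ant_inf),
        posterior_superior=pose(post_sup), posterior_inferior=pose(post_inf),
        spinous_distal=pose(spin_distal), spinous_proximal=pose(spin_proximal))
    true_measures = {
        "vertebral_height": (height_ant + height_post) / 2.0,
        "vertebral_depth": (depth_sup + depth_inf) / 2.0,
        "spinous_process_length": spinous_len,
        "body_to_spinous_length": body_to_spinous,
    }
    return pose(cloud), lm, true_measures


def damped_oscillation(amplitude: float = 10.0, frequency: float = 5.0,
                       decay: float = 10.0, duration: float = 0.2, dt: float = 1e-3,
                       noise_sd: float = 0.0, seed: int = 0) -> TimeSeries:
    """A e^(-decay t) sin(2 pi f t) + seeded Gaussian noise.

    ``frequency`` in Hz, ``duration``/``dt`` in seconds, ``decay`` in 1/s;
    times are reported in ms to match the toolkit's time unit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    values = amplitude * np.exp(-decay * t) * np.sin(2 * np.pi * frequency * t)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(scale=noise_sd, size=t.shape)
    return TimeSeries(t=t * 1000.0, values=values)


def strain_field(mesh: TetMesh, rule: str = "uniform", value: float = 0.1,
                 center=None, peak: float = 0.8, falloff: float = 5.0) -> np.ndarray:
    """Deterministic per-element symmetric strain tensors for erosion tests.

    rules: ``uniform`` (diag(value, 0, 0) everywhere), ``radial`` (magnitude
    value * r / r_max from the mesh centroid, uniaxial along the radius) and
    ``hotspot`` (Gaussian bump of height ``peak`` and length scale
    ``falloff`` mm around ``center``, on top of a ``value`` background).
    """
    centroids = mesh.nodes[mesh.elements].mean(axis=1)
    n = len(centroids)
    out = np.zeros((n, 3, 3))
    if rule == "uniform":
        out[:, 0, 0] = value
        return out
    if rule == "radial":
        c0 = centroids.mean(axis=0)
        rvec = centroids - c0
        r = np.linalg.norm(rvec, axis=1)
        rmax = r.max() if r.max() > 0 else 1.0
        mag = value * r / rmax
        dirs = np.where(r[:, None] > 0, rvec / np.maximum(r[:, None], 1e-300),
                        np.array([1.0, 0.0, 0.0]))
        out = mag[:, None, None] * np.einsum("ni,nj->nij", dirs, dirs)
        return out
    if rule == "hotspot":
        if center is None:
            center = centroids[0]
        d = np.linalg.norm(centroids - np.asarray(center, dtype=float), axis=1)
        mag = value + (peak - value) * np.exp(-((d / falloff) ** 2))
        out[:, 0, 0] = mag
        return out
    raise ValueError(f"unknown strain-field rule {rule!r}")
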