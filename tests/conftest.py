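import numpy as np
import pytest

from tethex import HexMesh, TetMesh


@pytest.fixture
def regular_tet() -> TetMesh:
    """Unit-edge regular tetrahedron."""
    nodes = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3) / 2, 0.0],
        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
    ])
    return TetMesh(nodes, [[0, 1, 2, 3]], part_label="regular_tet")


@pytest.fixture
def two_tets() -> TetMesh:
    """Two tetrahedra sharing the face (0, 1, 2)."""
    nodes = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.3, 0.3, -1.0],
    ])
    return TetMesh(nodes, [[0, 1, 2, 3], [0, 2, 1, 4]], part_label="two_tets")


@pytest.fixture
def unit_cube_hex() -> HexMesh:
    nodes = np.array([
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ], dtype=float)
    return HexMesh(nodes, [list(range(8))], part_label="unit_cube")


def random_small_tet_mesh(rng: np.random.Generator, max_cells: int = 3) -> TetMesh:
    """Small conformal lattice mesh with a random subset of cells kept."""
    from tethex.synth_fixtures import box_lattice_tet_mesh

    nx = int(rng.integers(1, max_cells + 1))
    ny = int(rng.integers(1, max_cells + 1))
    nz = int(rng.integers(1, max_cells + 1))
    mesh = box_lattice_tet_mesh(size=(nx, ny, nz), cell_edge=1.0)
    n = mesh.n_elements
    keep = rng.random(n) < 0.7
    if not keep.any():
        keep[0] = True
    used = np.unique(mesh.elements[keep])
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TetMesh(mesh.nodes[used], remap[mesh.elements[keep]])
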