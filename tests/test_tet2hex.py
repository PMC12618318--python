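"""Tet-to-hex conversion: counts, tiling, conformality, angle control."""

import numpy as np
import pytest

from tethex import (
    ConversionConfig,
    TetMesh,
    convert_tet_to_hex,
    mesh_volume,
    predict_quad_angles,
    subdivide_triangle,
)
from tethex.mesh_core import MeshError, enumerate_edges_faces
from tethex.quality import scaled_jacobian
from tethex.tet2hex import max_face_corner_angle

from conftest import random_small_tet_mesh

NO_SMOOTH = ConversionConfig(smoothing_iterations=0)


class TestSingleTet:
    def test_four_hexes_per_tet(self, regular_tet):
        res = convert_tet_to_hex(regular_tet)
        assert res.hex_mesh.n_elements == 4

    def test_node_count_and_provenance(self, regular_tet):
        res = convert_tet_to_hex(regular_tet)
        assert res.hex_mesh.n_nodes == 15  # 4 V + 6 E + 4 F + 1 T
        kinds = [k for k, _ in res.node_provenance.values()]
        assert kinds.count("vertex") == 4
        assert kinds.count("edge_midpoint") == 6
        assert kinds.count("face_centroid") == 4
        assert kinds.count("element_centroid") == 1

    def test_three_boundary_quads_per_triangle(self, regular_tet):
        res = convert_tet_to_hex(regular_tet)
        assert len(res.boundary_quads.faces) == 12  # 4 triangles x 3

    def test_volume_conserved_exactly(self, regular_tet):
        res = convert_tet_to_hex(regular_tet, NO_SMOOTH)
        assert mesh_volume(res.hex_mesh) == pytest.approx(
            mesh_volume(regular_tet), rel=1e-12)

    def test_regular_tet_needs_no_smoothing(self, regular_tet):
        res = convert_tet_to_hex(regular_tet)
        assert res.stats["smoothing_iterations_used"] == 0
        assert res.stats["max_face_corner_angle_deg"] == pytest.approx(120.0)
        assert len(res.flagged_elements) == 0

    def test_positive_corner_jacobians(self, regular_tet):
        res = convert_tet_to_hex(regular_tet, NO_SMOOTH)
        sj = np.atleast_1d(scaled_jacobian(res.hex_mesh.element_coords()))
        assert (sj > 0).all()
        # unit edge vectors pairwise at 60 deg: det = sqrt(Gram det) = sqrt(1/2)
        assert sj.min() == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_degenerate_tet_rejected(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 1e-15]])
        with pytest.raises(MeshError, match="degenerate"):
            convert_tet_to_hex(TetMesh(nodes, [[0, 1, 2, 3]]))


class TestTwoTets:
    def test_counting_identity(self, two_tets):
        res = convert_tet_to_hex(two_tets)
        assert res.hex_mesh.n_elements == 8
        assert res.hex_mesh.n_nodes == 23  # V+E+F+T = 5+9+7+2

    def test_conformal_shared_nodes(self, two_tets):
        res = convert_tet_to_hex(two_tets, NO_SMOOTH)
        coords = res.hex_mesh.nodes
        d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        np.fill_diagonal(d, 1.0)
        assert d.min() > 1e-9  # no duplicated coordinates anywhere

    def test_determinism(self, two_tets):
        a = convert_tet_to_hex(two_tets)
        b = convert_tet_to_hex(two_tets)
        np.testing.assert_array_equal(a.hex_mesh.elements, b.hex_mesh.elements)
        np.testing.assert_array_equal(a.hex_mesh.nodes, b.hex_mesh.nodes)


class TestRandomMeshes:
    @pytest.mark.parametrize("seed", range(6))
    def test_node_count_identity_vs_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        mesh = random_small_tet_mesh(rng)
        edges, faces = enumerate_edges_faces(mesh)
        res = convert_tet_to_hex(mesh, NO_SMOOTH)
        expected = mesh.n_nodes + len(edges) + len(faces) + mesh.n_elements
        assert res.hex_mesh.n_nodes == expected
        assert res.hex_mesh.n_elements == 4 * mesh.n_elements

    @pytest.mark.parametrize("seed", range(4))
    def test_volume_conservation_pre_smoothing(self, seed):
        rng = np.random.default_rng(100 + seed)
        mesh = random_small_tet_mesh(rng)
        res = convert_tet_to_hex(mesh, NO_SMOOTH)
        assert mesh_volume(res.hex_mesh) == pytest.approx(
            mesh_volume(mesh), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_all_corner_jacobians_positive(self, seed):
        rng = np.random.default_rng(200 + seed)
        mesh = random_small_tet_mesh(rng)
        res = convert_tet_to_hex(mesh, NO_SMOOTH)
        sj = np.atleast_1d(scaled_jacobian(res.hex_mesh.element_coords()))
        assert (sj > 0).all()

    def test_boundary_quads_triple_boundary_triangles(self):
        rng = np.random.default_rng(42)
        mesh = random_small_tet_mesh(rng)
        from tethex import boundary_surface

        n_tris = len(boundary_surface(mesh).faces)
        res = convert_tet_to_hex(mesh, NO_SMOOTH)
        assert len(res.boundary_quads.faces) == 3 * n_tris


class TestTriangleSubdivision:
    def test_equilateral_angles_exact(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        quads, prov = subdivide_triangle(tri)
        ang = predict_quad_angles([60.0, 60.0, 60.0])
        for row in ang:
            assert sorted(row) == pytest.approx([60, 90, 90, 120], abs=1e-9)
        # tiling: areas sum to the triangle area
        def quad_area(q):
            return (np.linalg.norm(np.cross(q[1] - q[0], q[2] - q[0]))
                    + np.linalg.norm(np.cross(q[2] - q[0], q[3] - q[0]))) / 2
        total = sum(quad_area(q) for q in quads)
        assert total == pytest.approx(np.sqrt(3) / 4, rel=1e-12)

    def test_right_isoceles_vertex_angle(self):
        # quad grown at the right-angle vertex keeps that 90 deg corner
        ang = predict_quad_angles([90.0, 45.0, 45.0])
        assert ang[0][0] == pytest.approx(90.0, abs=1e-9)

    def test_predicted_angles_match_measured(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        quads, _ = subdivide_triangle(tri)
        measured = []
        for q in quads:
            row = []
            for k in range(4):
                u = q[(k + 1) % 4] - q[k]
                v = q[(k - 1) % 4] - q[k]
                row.append(np.degrees(np.arccos(
                    u @ v / np.linalg.norm(u) / np.linalg.norm(v))))
            measured.append(row)
        predicted = predict_quad_angles([90.0, 45.0, 45.0])
        np.testing.assert_allclose(np.sort(measured, axis=None),
                                   np.sort(predicted, axis=None), atol=1e-9)

    def test_quad_angles_sum_360(self):
        for angles in ([60, 60, 60], [90, 45, 45], [100, 50, 30], [150, 20, 10]):
            out = predict_quad_angles(angles)
            np.testing.assert_allclose(out.sum(axis=1), 360.0, atol=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(MeshError):
            subdivide_triangle(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]]))


class TestAngleEnforcement:
    def _sheared_sliver(self):
        """A tet flattened and sheared enough to break the angle bound."""
        nodes = np.array([
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [2.0, 0.25, 0.0],
            [1.0, 0.1, 0.05],
        ])
        return TetMesh(nodes, [[0, 1, 2, 3]])

    def test_sliver_violates_before_enforcement(self):
        res = convert_tet_to_hex(self._sheared_sliver(), NO_SMOOTH)
        worst = max_face_corner_angle(res.hex_mesh.nodes, res.hex_mesh.elements)
        assert worst.max() > 140.0

    def test_repaired_or_flagged_dichotomy(self):
        res = convert_tet_to_hex(self._sheared_sliver(),
                                 ConversionConfig(smoothing_iterations=50))
        worst = max_face_corner_angle(res.hex_mesh.nodes, res.hex_mesh.elements)
        bad = np.flatnonzero(worst > 140.0 + 1e-9)
        np.testing.assert_array_equal(bad, res.flagged_elements)

    def test_flags_match_audited_angles(self, two_tets):
        res = convert_tet_to_hex(two_tets)
        worst = max_face_corner_angle(res.hex_mesh.nodes, res.hex_mesh.elements)
        np.testing.assert_array_equal(
            np.flatnonzero(worst > 140.0 + 1e-9), res.flagged_elements)

    def test_enforcement_repairs_lattice_sphere(self):
        from tethex.synth_fixtures import sphere_tet_mesh

        mesh = sphere_tet_mesh(8.0, 2.0)
        raw = convert_tet_to_hex(mesh, NO_SMOOTH)
        assert max_face_corner_angle(
            raw.hex_mesh.nodes, raw.hex_mesh.elements).max() > 140.0
        res = convert_tet_to_hex(mesh, ConversionConfig(smoothing_iterations=30))
        assert res.stats["max_face_corner_angle_deg"] <= 140.0
        assert len(res.flagged_elements) == 0
        assert res.stats["volume_drift_rel"] <= 0.01

    def test_boundary_preserved_during_smoothing(self):
        from tethex.synth_fixtures import sphere_tet_mesh
        from tethex import boundary_surface
        from tethex.morphometry import enclosed_volume

        mesh = sphere_tet_mesh(8.0, 2.0)
        res = convert_tet_to_hex(mesh, ConversionConfig(smoothing_iterations=30))
        # staircase boundary is a union of planar facets: smoothing must keep
        # the enclosed volume of the boundary exactly
        vol_in = enclosed_volume(boundary_surface(mesh))
        vol_out = enclosed_volume(res.boundary_quads)
        assert vol_out == pytest.approx(vol_in, rel=1e-9)
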