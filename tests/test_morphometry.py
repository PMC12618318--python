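"""Vertebral morphometry, thickness/volume measures and curve statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tethex.morphometry import (
    TimeSeries,
    VertebralLandmarks,
    body_to_spinous_length,
    curve_compare,
    dimensionless_disk_height,
    enclosed_volume,
    max_principal_strain,
    neck_flexion_angle,
    pca_reorient,
    spinous_process_length,
    surface_thickness,
    vertebral_depth,
    vertebral_height,
)
from tethex.mesh_core import MeshError, SurfaceMesh


def rect_landmarks(height=14.0, depth=16.0, origin=(0.0, 0.0, 0.0)):
    o = np.asarray(origin, float)
    return VertebralLandmarks(
        anterior_superior=o + [depth, 0, height],
        anterior_inferior=o + [depth, 0, 0],
        posterior_superior=o + [0, 0, height],
        posterior_inferior=o + [0, 0, 0],
        spinous_distal=o + [-30, 0, height / 2],
        spinous_proximal=o + [-10, 0, height / 2],
    )


def rigidly_move(lm: VertebralLandmarks, seed=0, scale=1.0):
    R = Rotation.random(random_state=seed).as_matrix()
    t = np.array([12.0, -7.0, 30.0])
    move = lambda p: scale * (R @ p) + t  # noqa: E731
    return VertebralLandmarks(*[move(getattr(lm, f)) for f in (
        "anterior_superior", "anterior_inferior", "posterior_superior",
        "posterior_inferior", "spinous_distal", "spinous_proximal")])


def icosphere_surface(radius, subdivisions=3, center=(0, 0, 0)):
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(s.vertices) + np.asarray(center, float),
                       np.asarray(s.faces, dtype=np.int64))


class TestBodyMeasures:
    def test_axis_aligned_rectangle(self):
        lm = rect_landmarks(14.0, 16.0)
        assert vertebral_height(lm) == pytest.approx(14.0)
        assert vertebral_depth(lm) == pytest.approx(16.0)

    def test_trapezoid_height_average(self):
        lm = rect_landmarks(14.0, 16.0)
        lm.anterior_superior = lm.anterior_inferior + np.array([0, 0, 12.0])
        assert vertebral_height(lm) == pytest.approx(13.0)

    def test_random_quadrilateral_matches_hand_computation(self):
        rng = np.random.default_rng(3)
        pts = {f: rng.uniform(-20, 20, 3) for f in (
            "anterior_superior", "anterior_inferior", "posterior_superior",
            "posterior_inferior", "spinous_distal", "spinous_proximal")}
        lm = VertebralLandmarks(**pts)
        ha = np.linalg.norm(pts["anterior_superior"] - pts["anterior_inferior"])
        hp = np.linalg.norm(pts["posterior_superior"] - pts["posterior_inferior"])
        assert vertebral_height(lm) == pytest.approx((ha + hp) / 2)

    def test_spinous_lengths(self):
        lm = rect_landmarks()
        lm.spinous_distal = np.array([30.0, 0, 0])
        lm.spinous_proximal = np.array([10.0, 0, 0])
        assert spinous_process_length(lm) == pytest.approx(20.0)
        posterior_mid = (lm.posterior_superior + lm.posterior_inferior) / 2
        assert body_to_spinous_length(lm) == pytest.approx(
            np.linalg.norm(lm.spinous_distal - posterior_mid))

    def test_rigid_invariance(self):
        lm = rect_landmarks(13.0, 15.5)
        moved = rigidly_move(lm, seed=5)
        assert vertebral_height(moved) == pytest.approx(vertebral_height(lm))
        assert vertebral_depth(moved) == pytest.approx(vertebral_depth(lm))
        assert spinous_process_length(moved) == pytest.approx(
            spinous_process_length(lm))


class TestDiskHeight:
    def _pair(self, gap=5.0):
        lower = rect_landmarks(14.0, 15.0)
        upper = rect_landmarks(14.0, 15.0, origin=(0.0, 0.0, 14.0 + gap))
        return upper, lower

    def test_parallel_plates_plain_ratio(self):
        upper, lower = self._pair(gap=5.0)
        assert dimensionless_disk_height(upper, lower) == pytest.approx(5.0 / 15.0)

    def test_rigid_and_scale_invariance(self):
        upper, lower = self._pair(gap=5.0)
        u2 = rigidly_move(upper, seed=9, scale=2.5)
        l2 = rigidly_move(lower, seed=9, scale=2.5)
        assert dimensionless_disk_height(u2, l2) == pytest.approx(5.0 / 15.0)

    def test_wedged_disk_matches_coordinate_oracle(self):
        # lower plate horizontal, upper endplate tilted by 10 degrees
        lower = rect_landmarks(14.0, 15.0)
        ang = np.radians(10.0)
        R = np.array([[np.cos(ang), 0, -np.sin(ang)], [0, 1, 0],
                      [np.sin(ang), 0, np.cos(ang)]])
        upper = rect_landmarks(14.0, 15.0, origin=(0, 0, 19.0))
        pivot = upper.posterior_inferior.copy()
        upper = VertebralLandmarks(*[(R @ (getattr(upper, f) - pivot)) + pivot for f in (
            "anterior_superior", "anterior_inferior", "posterior_superior",
            "posterior_inferior", "spinous_distal", "spinous_proximal")])
        got = dimensionless_disk_height(upper, lower)
        # oracle: explicit bisector construction in the x-z plane
        a0, a1 = upper.posterior_inferior, upper.anterior_inferior
        b0, b1 = lower.posterior_superior, lower.anterior_superior
        u = (a1 - a0) / np.linalg.norm(a1 - a0)
        w = (b1 - b0) / np.linalg.norm(b1 - b0)
        bis = (u + w) / np.linalg.norm(u + w)
        gap = (a0 + a1) / 2 - (b0 + b1) / 2
        h = np.linalg.norm(gap - (gap @ bis) * bis)
        depth = (vertebral_depth(upper) + vertebral_depth(lower)) / 2
        assert got == pytest.approx(h / depth, rel=1e-12)

    def test_interpenetration_flagged(self):
        upper, lower = self._pair(gap=-2.0)
        with pytest.warns(UserWarning, match="intersect"):
            v = dimensionless_disk_height(upper, lower)
        assert v < 0


class TestPCAReorient:
    def _box_cloud(self, rng, extents=(10.0, 4.0, 2.0), n=4000):
        return rng.uniform(-1, 1, (n, 3)) * np.asarray(extents)

    def test_aligned_box_identity(self):
        rng = np.random.default_rng(0)
        pts = self._box_cloud(rng)
        res = pca_reorient(pts)
        np.testing.assert_allclose(np.abs(res.rotation), np.eye(3), atol=0.05)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        pts = self._box_cloud(rng)
        res0 = pca_reorient(pts)
        R = Rotation.random(random_state=4).as_matrix()
        posed = pts @ R.T + np.array([5.0, 6.0, 7.0])
        # principal axes of the posed cloud are the rotated original axes
        res = pca_reorient(posed, reference_directions=res0.rotation @ R.T)
        np.testing.assert_allclose(res.rotation @ R, res0.rotation, atol=1e-9)
        # the intrinsic frame is pose-independent: aligned clouds coincide
        np.testing.assert_allclose(res.aligned_points, res0.aligned_points,
                                   atol=1e-9)

    def test_round_trip_restores_coordinates(self):
        rng = np.random.default_rng(2)
        pts = self._box_cloud(rng)
        res = pca_reorient(pts)
        back = res.aligned_points @ res.rotation + res.centroid
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_isotropic_cloud_degenerate(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(MeshError):
            pca_reorient(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pca_reorient(np.zeros((3, 3)))


class TestSurfaces:
    def test_concentric_sphere_thickness(self):
        inner = icosphere_surface(80.0)
        outer = icosphere_surface(85.0)
        t = surface_thickness(inner, outer, mode="minimum")
        assert t == pytest.approx(5.0, abs=0.15)  # faceting error only
        vals, missing = surface_thickness(
            inner, outer, mode="at_sites", sites=[[0, 0, 85.0], [85.0, 0, 0]])
        assert not missing.any()
        np.testing.assert_allclose(vals, 5.0, atol=0.2)

    def test_offset_inner_sphere_closest_gap(self):
        inner = icosphere_surface(40.0, center=(3.0, 0, 0))
        outer = icosphere_surface(50.0)
        t = surface_thickness(inner, outer, mode="minimum")
        assert t == pytest.approx(50.0 - 40.0 - 3.0, abs=0.2)

    def test_site_over_hole_missing(self):
        inner = icosphere_surface(40.0)
        # keep only a bottom cap; an equatorial inward ray misses it entirely
        keep = inner.nodes[inner.faces].mean(axis=1)[:, 2] < -30.0
        inner_patch = SurfaceMesh(inner.nodes, inner.faces[keep])
        outer = icosphere_surface(50.0)
        vals, missing = surface_thickness(inner_patch, outer, mode="at_sites",
                                          sites=[[50.0, 0, 0]])
        assert missing[0]

    def test_enclosed_volume_cube_unit_conversion(self):
        nodes = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0],
                          [0, 0, 10], [10, 0, 10], [10, 10, 10], [0, 10, 10]], float)
        from tethex import HexMesh, boundary_surface

        surf = boundary_surface(HexMesh(nodes, [list(range(8))]))
        assert enclosed_volume(surf) == pytest.approx(1.0)  # cm^3

    def test_enclosed_volume_icosphere(self):
        surf = icosphere_surface(50.0, subdivisions=4)
        assert enclosed_volume(surf) == pytest.approx(523.6, rel=0.01)

    def test_inverted_orientation_warns_same_magnitude(self):
        surf = icosphere_surface(20.0)
        flipped = SurfaceMesh(surf.nodes, surf.faces[:, ::-1])
        with pytest.warns(UserWarning, match="orientation"):
            v = enclosed_volume(flipped)
        assert v == pytest.approx(enclosed_volume(surf))

    def test_open_surface_rejected_with_edge_count(self):
        surf = icosphere_surface(20.0, subdivisions=1)
        open_surf = SurfaceMesh(surf.nodes, surf.faces[:-1])
        with pytest.raises(MeshError, match="3 boundary edge"):
            enclosed_volume(open_surf)


class TestFlexionAngleAndStrain:
    UP = np.array([0.0, 0.0, 1.0])
    N = np.array([0.0, 1.0, 0.0])

    def test_vertical_line_zero(self):
        assert neck_flexion_angle([0, 0, 100.0], [0, 0, 0], self.UP, self.N) == pytest.approx(0.0)

    def test_horizontal_line_ninety(self):
        a = neck_flexion_angle([100.0, 0, 0], [0, 0, 0], self.UP, self.N)
        assert abs(a) == pytest.approx(90.0)

    def test_arbitrary_matches_trigonometry(self):
        f = np.array([30.0, 5.0, 80.0])
        c = np.array([0.0, -3.0, 0.0])
        got = neck_flexion_angle(f, c, self.UP, self.N)
        line = f - c
        expected = np.degrees(np.arctan2(line[0], line[2]))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_line_in_plane_normal_undefined(self):
        with pytest.raises(ValueError):
            neck_flexion_angle([0, 10.0, 0], [0, 0, 0], self.UP, self.N)

    def test_max_principal_strain_values(self):
        assert max_principal_strain(np.diag([0.1, 0.05, -0.2])) == pytest.approx(0.1)
        assert max_principal_strain(np.zeros((3, 3))) == 0.0

    def test_batch_peak_location(self):
        field = np.zeros((10, 3, 3))
        field[:, 0, 0] = np.linspace(0, 0.5, 10)
        vals, peak, idx = max_principal_strain(field)
        assert idx == 9 and peak == pytest.approx(0.5)


class TestCurveCompare:
    def test_identical_series(self):
        t = np.linspace(0, 100, 200)
        a = TimeSeries(t, np.sin(t / 10))
        out = curve_compare(a, TimeSeries(t, np.sin(t / 10)))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["peak_a"] == out["peak_b"]
        assert out["peak_time_a"] == out["peak_time_b"]

    def test_negation_anticorrelated(self):
        t = np.linspace(0, 100, 200)
        a = TimeSeries(t, np.sin(t / 10))
        out = curve_compare(a, TimeSeries(t, -np.sin(t / 10)))
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_sin_vs_cos_orthogonal(self):
        t = np.linspace(0.0, 4 * np.pi, 4001)
        a = TimeSeries(t, np.sin(t))
        b = TimeSeries(t, np.cos(t))
        assert abs(curve_compare(a, b)["pearson_r"]) < 1e-3

    def test_resampling_on_overlap(self):
        a = TimeSeries(np.linspace(0, 10, 101), np.linspace(0, 10, 101))
        b = TimeSeries(np.linspace(5, 15, 51), np.linspace(5, 15, 51))
        out = curve_compare(a, b)  # on the overlap both curves equal t
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_insufficient_overlap_rejected(self):
        a = TimeSeries([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 2.0, 3.0])
        b = TimeSeries([2.9, 3.5, 4.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="overlap"):
            curve_compare(a, b)
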