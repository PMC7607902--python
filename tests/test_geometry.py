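"""Vertex circles, tube meshing and microregion geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eggsim as eg
from eggsim.errors import (
    DegenerateSegmentError,
    InvalidParameterError,
)
from eggsim.geometry import segment_rotation


class TestVertexCircle:
    def test_quadrant_points_on_unit_circle(self):
        pts = eg.make_vertex_circle(1.0, 4)
        expected = {(0, 1, 0), (-1, 0, 0), (0, -1, 0), (1, 0, 0)}
        got = {tuple(np.round(p, 12)) for p in pts}
        assert got == expected

    def test_all_points_at_band_radius(self):
        # the cylinder benchmark's band radius, 0.0125 m = 1.25 cm
        pts = eg.make_vertex_circle(1.25, 100)
        assert pts.shape == (100, 3)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.25, atol=1e-12)
        np.testing.assert_allclose(pts[:, 2], 0.0, atol=1e-15)

    def test_three_samples_form_equilateral_triangle(self):
        pts = eg.make_vertex_circle(2.0, 3)
        d = [np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3)]
        np.testing.assert_allclose(d, d[0])

    @pytest.mark.parametrize("radius,samples", [(0.0, 10), (-1.0, 10), (1.0, 2)])
    def test_invalid_parameters_rejected(self, radius, samples):
        with pytest.raises(InvalidParameterError):
            eg.make_vertex_circle(radius, samples)


class TestOrientAndPlace:
    def test_vertical_segment_is_pure_translation(self):
        local = eg.make_vertex_circle(1.0, 4)
        placed = eg.orient_and_place_circle(local, [0, 0, 5], [0, 0, 9])
        np.testing.assert_allclose(placed, local + [0, 0, 5], atol=1e-12)

    def test_x_segment_circle_normal_along_x(self):
        local = eg.make_vertex_circle(1.0, 16)
        placed = eg.orient_and_place_circle(local, [2, 0, 0], [5, 0, 0])
        rel = placed - np.array([2.0, 0.0, 0.0])
        np.testing.assert_allclose(rel @ [1, 0, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(rel, axis=1), 1.0, atol=1e-12)

    def test_oblique_segment_perpendicular_and_radial(self):
        tangent = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        local = eg.make_vertex_circle(1.0, 64)
        c_n = np.array([0.3, -0.2, 1.1])
        placed = eg.orient_and_place_circle(local, c_n, c_n + 2.0 * tangent)
        rel = placed - c_n
        assert np.max(np.abs(rel @ tangent)) < 1e-9
        assert np.max(np.abs(np.linalg.norm(rel, axis=1) - 1.0)) < 1e-9

    def test_zero_length_segment_rejected(self):
        local = eg.make_vertex_circle(1.0, 8)
        with pytest.raises(DegenerateSegmentError):
            eg.orient_and_place_circle(local, [1, 2, 3], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.floats(-5, 5) for _ in range(3)]))
    def test_any_direction_yields_perpendicular_circle(self, direction):
        d = np.asarray(direction)
        norm = np.linalg.norm(d)
        if norm < 1e-6:
            return
        local = eg.make_vertex_circle(1.0, 12)
        placed = eg.orient_and_place_circle(local, [0, 0, 0], d)
        assert np.max(np.abs(placed @ (d / norm))) < 1e-9


class TestSegmentRotation:
    @pytest.mark.parametrize("direction", [
        (1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, -1), (1, 1, 1), (-2, 0.5, -3),
    ])
    def test_rotation_is_orthonormal_and_proper(self, direction):
        rot, _ = segment_rotation(np.asarray(direction, dtype=float))
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)
        assert abs(np.linalg.det(rot) - 1.0) < 1e-12

    def test_vertical_segment_reuses_previous_azimuth(self):
        _, az = segment_rotation(np.array([0.0, 0.0, 1.0]), fallback_azimuth=0.7)
        assert az == 0.7


class TestBuildTubeMesh:
    def test_cylinder_benchmark_discretization(self):
        # 0.10 m cylinder split by 910 circles -> 909 rings of 0.00011 m
        sc = eg.make_cylinder_scenario()
        mesh = sc.build_mesh()
        assert mesh.n_rings == 909
        np.testing.assert_allclose(mesh.ring_widths, 10.0 / 909.0, rtol=1e-12)

    def test_two_point_centerline_gives_single_ring(self):
        cl = eg.Centerline([[0, 0, 0], [0, 0, 2]], [1.0, 1.0])
        mesh = eg.build_tube_mesh(cl, 8)
        assert mesh.n_rings == 1
        assert mesh.vertices.shape == (2, 8, 3)

    def test_helix_mesh_invariants(self, helix_centerline, helix_mesh):
        mesh = helix_mesh
        pts = helix_centerline.points
        # circles lie at the right radius around their centerline point
        for n in range(mesh.n_circles):
            rel = mesh.vertices[n] - pts[n]
            np.testing.assert_allclose(
                np.linalg.norm(rel, axis=1), helix_centerline.radii[n], atol=1e-9
            )
            if n < mesh.n_circles - 1:
                tangent = pts[n + 1] - pts[n]
                tangent = tangent / np.linalg.norm(tangent)
                assert np.max(np.abs(rel @ tangent)) <= 1e-9 * helix_centerline.radii[n]
        # all quads non-degenerate
        for n in range(mesh.n_rings):
            assert np.all(mesh.ring_geometry(n)["areas"] > 0.0)

    def test_degenerate_centerline_rejected_with_index(self):
        with pytest.raises(DegenerateSegmentError, match="1"):
            eg.Centerline([[0, 0, 0], [0, 0, 1], [0, 0, 1]], [1, 1, 1])

    def test_equivariance_under_z_rotation_and_translation(self, helix_centerline):
        angle = 0.83
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        shift = np.array([1.0, -2.0, 0.5])
        mesh = eg.build_tube_mesh(helix_centerline, 16)
        moved = eg.build_tube_mesh(
            helix_centerline.transformed(rot, shift), 16
        )
        np.testing.assert_allclose(
            moved.vertices, mesh.vertices @ rot.T + shift, atol=1e-9
        )

    def test_general_rotation_preserves_circles_as_sets(self, helix_centerline):
        # the circumferential phase is anchored to the global frame, so only
        # the circle (not the vertex labelling) is equivariant here
        angle = 1.1
        axis = np.array([1.0, 2.0, 0.5])
        axis /= np.linalg.norm(axis)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        mesh = eg.build_tube_mesh(helix_centerline.transformed(rot), 24)
        pts = helix_centerline.points @ rot.T
        for n in (0, 10, 30):
            rel = mesh.vertices[n] - pts[n]
            tangent = pts[min(n, 48) + 1] - pts[min(n, 48)]
            tangent /= np.linalg.norm(tangent)
            np.testing.assert_allclose(
                np.linalg.norm(rel, axis=1), helix_centerline.radii[n], atol=1e-9
            )
            assert np.max(np.abs(rel @ tangent)) < 1e-9


class TestMicroregion:
    def test_axis_aligned_quad_cross_product(self):
        cl = eg.Centerline([[0, 0, 0], [0, 0, 1]], [1.0, 1.0])
        mesh = eg.build_tube_mesh(cl, 4)
        region = eg.microregion_geometry(mesh, 0, 0)
        # edges: circumferential chord and the +z axial edge
        a, b, _, d = mesh.quad_corners(0)
        expected = np.cross(b[0] - a[0], d[0] - a[0])
        np.testing.assert_allclose(region.area_vector, expected)
        assert region.area == pytest.approx(np.linalg.norm(expected))
        np.testing.assert_allclose(
            region.center, 0.5 * (mesh.quad_corners(0)[2][0] + a[0])
        )

    def test_area_vector_antisymmetry(self):
        e1, e2 = np.array([1.0, 0.2, 0.0]), np.array([0.0, 1.0, 0.3])
        np.testing.assert_allclose(np.cross(e1, e2), -np.cross(e2, e1))

    def test_ring_area_converges_to_lateral_area(self):
        # cylinder fixture ring: 2π·1.25·w within 0.1% at M = 100
        w = 10.0 / 909.0
        cl = eg.Centerline([[0, 0, 0], [0, 0, w]], [1.25, 1.25])
        mesh = eg.build_tube_mesh(cl, 100)
        total = float(np.sum(mesh.ring_geometry(0)["areas"]))
        exact = 2.0 * np.pi * 1.25 * w
        assert abs(total - exact) / exact < 1e-3

    def test_frustum_lateral_area(self):
        # a tapered tube's total quad area -> cone frustum lateral area
        # π (r1 + r2) · slant.  The per-quad cross product is a one-sided
        # (lower-circle) parallelogram estimate, first order in the ring
        # width, so the axial direction must be subdivided too.
        r1, r2, length, n = 1.5, 0.9, 4.0, 401
        cl = eg.Centerline(
            np.column_stack((np.zeros(n), np.zeros(n),
                             np.linspace(0.0, length, n))),
            np.linspace(r1, r2, n))
        mesh = eg.build_tube_mesh(cl, 100)
        total = sum(float(np.sum(mesh.ring_geometry(k)["areas"]))
                    for k in range(mesh.n_rings))
        exact = np.pi * (r1 + r2) * np.hypot(length, r1 - r2)
        assert abs(total - exact) / exact < 1e-3

    def test_outward_normals_point_away_from_axis(self, cylinder_mesh):
        geom = cylinder_mesh.ring_geometry(400)
        radial = geom["centers"] - [0.0, 0.0, 0.0]
        radial[:, 2] = 0.0
        dots = np.einsum("ij,ij->i", geom["outward_normals"], radial)
        assert np.all(dots > 0.0)

    def test_index_bounds_checked(self, helix_mesh):
        with pytest.raises(IndexError):
            eg.microregion_geometry(helix_mesh, 99, 0)
        with pytest.raises(IndexError):
            eg.microregion_geometry(helix_mesh, 0, helix_mesh.n_rings)
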