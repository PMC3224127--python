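"""Simplex-mesh geometry: construction, differential quantities,
refinement, rasterization."""

import numpy as np
import pytest

from multiseg import ScalarVolume, build_simplex_sphere, rasterize, refine
from multiseg.mesh import (
    GeometryError,
    MeshTopologyError,
    SimplexMesh,
    mean_curvature,
    simplex_angle,
    simplex_geometry,
    vertex_normal,
    vertex_normals,
)

SPHERE_VOL = 4.0 / 3.0 * np.pi * 5.0**3  # radius-5 sphere


class TestConstruction:
    def test_dual_of_icosahedron_has_20_three_connected_vertices(self, unit_sphere0):
        assert unit_sphere0.n_vertices == 20
        assert unit_sphere0.neighbors.shape == (20, 3)
        for i in range(20):
            assert len(set(unit_sphere0.neighbors[i])) == 3

    def test_one_subdivision_gives_80_vertices(self, unit_sphere1):
        assert unit_sphere1.n_vertices == 80

    def test_vertices_projected_onto_sphere(self):
        center = np.array([3.0, -2.0, 7.0])
        m = build_simplex_sphere(center, 4.5, 1)
        radii = np.linalg.norm(m.vertices - center, axis=1)
        assert np.allclose(radii, 4.5, atol=1e-9)

    def test_neighbour_relation_symmetric_and_closed(self, unit_sphere1):
        nb = unit_sphere1.neighbors
        for i in range(len(nb)):
            for j in nb[i]:
                assert i in nb[j]
        assert unit_sphere1.is_closed()

    def test_euler_characteristic_is_2(self, unit_sphere1):
        assert unit_sphere1.euler_characteristic() == 2

    @pytest.mark.parametrize("radius", [0.0, -1.0])
    def test_nonpositive_radius_rejected(self, radius):
        with pytest.raises(ValueError):
            build_simplex_sphere((0, 0, 0), radius, 1)

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            build_simplex_sphere((0, 0, 0), 1.0, -1)

    def test_bad_connectivity_rejected(self, unit_sphere0):
        nb = unit_sphere0.neighbors.copy()
        nb[0] = [1, 1, 2]  # duplicate neighbour
        with pytest.raises(MeshTopologyError):
            SimplexMesh(
                unit_sphere0.vertices.copy(), nb,
                unit_sphere0.tri_faces.copy(),
                [r.copy() for r in unit_sphere0.rings],
            )


class TestDifferentialGeometry:
    def test_flat_vertex_has_zero_angle_and_curvature(self):
        # place vertex 0 exactly in its neighbours' plane
        m = build_simplex_sphere((0, 0, 0), 1.0, 1)
        geo = simplex_geometry(m)
        m.vertices[0] = geo["foot"][0]
        assert abs(simplex_angle(m, 0)) < 1e-12
        assert abs(mean_curvature(m, 0)) < 1e-12

    def test_sphere_angles_constant_by_symmetry(self, unit_sphere0):
        angles = [simplex_angle(unit_sphere0, i) for i in range(20)]
        assert max(angles) - min(angles) < 1e-6
        assert min(angles) > 0

    def test_angle_monotone_in_normal_displacement(self, unit_sphere1):
        m = unit_sphere1.copy()
        geo = simplex_geometry(m)
        flat = geo["foot"][0]
        n = geo["n"][0]
        prev = None
        for t in np.linspace(0.0, 0.1, 6):
            m.vertices[0] = flat + t * n
            a = simplex_angle(m, 0)
            if prev is not None:
                assert a > prev
            prev = a

    def test_normals_point_radially_outward(self, unit_sphere2):
        n = vertex_normals(unit_sphere2)
        radial = unit_sphere2.vertices / np.linalg.norm(
            unit_sphere2.vertices, axis=1, keepdims=True
        )
        assert np.einsum("ij,ij->i", n, radial).min() > 0.99

    def test_sphere_curvature_matches_1_over_r(self):
        for r in (1.0, 5.0):
            m = build_simplex_sphere((0, 0, 0), r, 2)
            H = [mean_curvature(m, i) for i in range(0, m.n_vertices, 41)]
            assert np.allclose(H, 1.0 / r, rtol=0.05)

    def test_angle_and_curvature_rigid_rotation_invariant(self, unit_sphere1):
        rng = np.random.default_rng(11)
        base_angles = np.array([simplex_angle(unit_sphere1, i) for i in range(8)])
        base_H = np.array([mean_curvature(unit_sphere1, i) for i in range(8)])
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            m = unit_sphere1.copy()
            m.vertices = m.vertices @ Q.T + rng.normal(size=3)
            ang = np.array([simplex_angle(m, i) for i in range(8)])
            H = np.array([mean_curvature(m, i) for i in range(8)])
            assert np.allclose(ang, base_angles, atol=1e-8)
            assert np.allclose(H, base_H, atol=1e-8)

    def test_degenerate_neighbours_raise(self, unit_sphere1):
        m = unit_sphere1.copy()
        i, j, k = m.neighbors[0]
        # collinear neighbour triple
        m.vertices[j] = m.vertices[i] + 1.0
        m.vertices[k] = m.vertices[i] + 2.0
        with pytest.raises(GeometryError):
            simplex_angle(m, 0)
        with pytest.raises(GeometryError):
            vertex_normal(m, 0)

    def test_vertex_index_out_of_range(self, unit_sphere0):
        with pytest.raises(IndexError):
            simplex_angle(unit_sphere0, 20)


class TestRefine:
    def test_vertex_count_at_least_doubles(self, unit_sphere0):
        fine = refine(unit_sphere0)
        assert fine.n_vertices >= 2 * unit_sphere0.n_vertices
        for i in range(fine.n_vertices):
            assert len(set(fine.neighbors[i])) == 3

    def test_refined_sphere_stays_near_sphere(self, unit_sphere1):
        fine = refine(unit_sphere1)
        dev = np.abs(np.linalg.norm(fine.vertices, axis=1) - 1.0)
        assert dev.max() < 0.05

    def test_refine_twice_quadruples_at_least(self, unit_sphere0):
        twice = refine(refine(unit_sphere0))
        assert twice.n_vertices >= 4 * unit_sphere0.n_vertices

    def test_refine_preserves_euler_characteristic(self, unit_sphere1):
        assert refine(unit_sphere1).euler_characteristic() == 2

    def test_self_intersecting_input_warns_but_proceeds(self, unit_sphere1, caplog):
        import logging

        m = unit_sphere1.copy()
        # push one vertex through the far side of the mesh
        m.vertices[0] = -2.5 * m.vertices[0]
        with caplog.at_level(logging.WARNING, logger="multiseg.mesh"):
            fine = refine(m)
        assert fine.n_vertices >= 2 * m.n_vertices
        assert any("self-intersecting" in r.message for r in caplog.records)


class TestRasterize:
    def test_sphere_volume_within_10_percent(self, grid20):
        m = build_simplex_sphere((9.5, 9.5, 9.5), 5.0, 2)
        mask = rasterize(m, grid20)
        assert abs(mask.volume_voxels - SPHERE_VOL) / SPHERE_VOL < 0.10

    def test_mesh_outside_grid_gives_empty_mask(self, grid20):
        m = build_simplex_sphere((100.0, 100.0, 100.0), 5.0, 1)
        assert rasterize(m, grid20).volume_voxels == 0

    def test_translation_by_one_voxel_translates_mask(self):
        grid = ScalarVolume(np.zeros((24, 24, 24)), [1, 1, 1], [0, 0, 0])
        m = build_simplex_sphere((10.3, 10.7, 11.1), 5.0, 2)
        a = rasterize(m, grid).values
        m2 = m.copy()
        m2.vertices = m.vertices + [1.0, 0.0, 0.0]
        b = rasterize(m2, grid).values
        assert np.array_equal(a[:-1, :, :], b[1:, :, :])

    def test_volume_error_halves_with_grid_resolution(self):
        m = build_simplex_sphere((9.5, 9.5, 9.5), 5.0, 3)
        coarse = rasterize(m, ScalarVolume(np.zeros((20, 20, 20)), [1] * 3, [0] * 3))
        fine = rasterize(
            m, ScalarVolume(np.zeros((40, 40, 40)), [0.5] * 3, [0] * 3)
        )
        err_c = abs(coarse.volume_mm3 - SPHERE_VOL) / SPHERE_VOL
        err_f = abs(fine.volume_mm3 - SPHERE_VOL) / SPHERE_VOL
        assert err_f <= err_c / 2.0

    def test_agrees_with_independent_containment_oracle(self):
        # independent even-odd oracle: Moller-Trumbore ray casting along +x
        # (the implementation integrates crossings along z)
        grid = ScalarVolume(np.zeros((14, 14, 14)), [1, 1, 1], [0, 0, 0])
        m = build_simplex_sphere((6.3, 6.8, 6.5), 4.0, 1)
        mask = rasterize(m, grid)
        pts, faces = m.surface_points_faces()
        tri = pts[faces]
        v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
        d = np.array([1.0, 0.0, 0.0])
        h = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, h)
        ok_t = np.abs(det) > 1e-12
        idx = np.argwhere(np.ones(grid.shape, dtype=bool)).astype(float)
        idx += [1.7e-7, 2.3e-7, 0.0]  # avoid edge-exact rays
        agree = 0
        for p, got in zip(idx, mask.values.ravel().astype(bool)):
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) / det
            q = np.cross(s, e1)
            v = np.einsum("ij,j->i", q, d) / det
            t = np.einsum("ij,ij->i", q, e2) / det
            hits = ok_t & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            agree += (int(hits.sum()) % 2 == 1) == got
        assert agree / len(idx) > 0.995

    def test_anisotropic_grid_volume_matches_analytic(self):
        grid = ScalarVolume(np.zeros((40, 20, 14)), [0.5, 1.0, 1.5], [0, 0, 0])
        m = build_simplex_sphere((9.5, 9.5, 9.5), 5.0, 2)
        mask = rasterize(m, grid)
        assert abs(mask.volume_mm3 - SPHERE_VOL) / SPHERE_VOL < 0.10
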