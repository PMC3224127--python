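"""Force terms and the motion update."""

import numpy as np
import pytest

from multiseg import (
    BinaryMask,
    ScalarVolume,
    StageParameters,
    balloon_forces,
    build_simplex_sphere,
    collision_forces,
    edge_forces,
    gradient_force,
    gradient_forces,
    internal_forces,
    step,
)
from multiseg.forces import ForceError, external_forces_sum
from multiseg.mesh import simplex_geometry, vertex_normals


def _uniform(shape=(24, 24, 24), value=0.0):
    return ScalarVolume(np.full(shape, value, dtype=float), [1, 1, 1], [0, 0, 0])


class TestStageParameters:
    @pytest.mark.parametrize("field,value", [
        ("w_internal", 1.2), ("w_balloon", -0.1), ("w_collision", 2.0),
    ])
    def test_weights_must_be_in_unit_interval(self, field, value):
        with pytest.raises(ValueError):
            StageParameters(**{field: value})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            StageParameters(t_low=1.0, t_high=-0.99)

    def test_smoothness_scale_positive(self):
        with pytest.raises(ValueError):
            StageParameters(smoothness_scale=0)


class TestInternalForce:
    def test_zero_at_reference_configuration(self, unit_sphere0):
        # all 20 dodecahedron vertices are equivalent, so the constructed
        # geometry is an exact equilibrium of the internal force
        f = internal_forces(unit_sphere0, StageParameters())
        assert np.abs(f).max() < 1e-10

    def test_tangential_perturbation_is_restored(self, unit_sphere1):
        m = unit_sphere1.copy()
        geo = simplex_geometry(m)
        n = geo["n"][0]
        tangent = np.cross(n, [0.0, 0.0, 1.0])
        tangent /= np.linalg.norm(tangent)
        m.vertices[0] = m.vertices[0] + 0.05 * tangent
        f = internal_forces(m, StageParameters())
        assert np.dot(f[0], -tangent) > 0  # pulls back against the push

    def test_high_smoothness_scale_smooths_noisy_sphere_better(self):
        rng = np.random.default_rng(5)

        def run_smoothing(scale):
            m = build_simplex_sphere((0, 0, 0), 5.0, 2)
            radial = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
            m.vertices = m.vertices + radial * rng.normal(0, 0.15, (m.n_vertices, 1))
            m.prev_positions = m.vertices.copy()
            params = StageParameters(smoothness_scale=scale)
            for _ in range(10):
                step(m, 0.9 * internal_forces(m, params), params)
            return np.var(np.linalg.norm(m.vertices, axis=1))

        rng = np.random.default_rng(5)
        var_high = run_smoothing(12)
        rng = np.random.default_rng(5)
        var_low = run_smoothing(3)
        assert var_high < var_low


class TestGradientForce:
    def test_pulls_toward_step_edge(self):
        vol = _uniform()
        vol.values[:, :, 12:] = 100.0  # step edge at z ~ 11.5
        from scipy.ndimage import gaussian_gradient_magnitude

        gm = vol.like(gaussian_gradient_magnitude(vol.values, 1.0))
        # top vertex sits at z ~ 10.5, two voxels below the edge at ~ 11.5
        m = build_simplex_sphere((12.0, 12.0, 7.5), 3.0, 1)
        f = gradient_forces(gm, m, StageParameters(gradient_search_radius=3))
        top = int(np.argmax(m.vertices[:, 2]))
        assert f[top][2] > 0  # pulled toward higher z (the edge)

    def test_uniform_image_gives_zero_force(self, unit_sphere1):
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        f = gradient_forces(_uniform(), m, StageParameters())
        assert np.abs(f).max() == 0.0

    def test_vertex_outside_volume_gives_zero_force(self):
        m = build_simplex_sphere((100, 100, 100), 3.0, 0)
        f = gradient_forces(_uniform(), m, StageParameters())
        assert np.abs(f).max() == 0.0

    def test_ties_broken_by_distance_then_lowest_index(self):
        vol = _uniform((9, 9, 9))
        m = build_simplex_sphere((4.0, 4.0, 4.0), 1.0, 0)
        m.vertices[0] = np.array([4.0, 4.0, 4.0])
        # two equal maxima at different distances from vertex 0
        vol.values[4, 4, 6] = 5.0   # distance 2
        vol.values[4, 4, 3] = 5.0   # distance 1 -> wins
        f = gradient_force(vol, m, 0, StageParameters(gradient_search_radius=3))
        n = vertex_normals(m)[0]
        assert np.dot(f[0:3], n) * np.dot(np.array([4, 4, 3]) - m.vertices[0], n) >= 0
        # equal value, equal distance -> lowest flat voxel index
        vol2 = _uniform((9, 9, 9))
        vol2.values[3, 4, 4] = 5.0  # flat index lower
        vol2.values[5, 4, 4] = 5.0
        from multiseg.forces import _search_maximum

        pts, vals, found = _search_maximum(vol2, m.vertices[:1], 3)
        assert found[0]
        assert np.allclose(pts[0], [3, 4, 4])


class TestEdgeForce:
    def test_bright_plane_on_normal_line_attracts(self):
        vol = _uniform()
        vol.values[:, :, 16] = 200.0
        m = build_simplex_sphere((12.0, 12.0, 12.0), 3.0, 1)
        params = StageParameters(gradient_search_radius=3)
        f = edge_forces(vol, m, params)
        top = int(np.argmax(m.vertices[:, 2]))  # at z=15, plane 1 voxel above
        assert f[top][2] > 0

    def test_zero_weight_contributes_nothing(self):
        shape = (5, 3)
        rng = np.random.default_rng(0)
        parts = [rng.normal(size=shape) for _ in range(4)]
        total = external_forces_sum(
            StageParameters(w_edge=0.0, w_gradient=1.0, w_balloon=1.0, w_collision=1.0),
            parts[0], parts[1], parts[2], parts[3],
        )
        assert np.allclose(total, parts[0] + parts[2] + parts[3])

    def test_normal_line_exiting_volume_is_truncated_silently(self):
        vol = _uniform((10, 10, 10))
        m = build_simplex_sphere((5.0, 5.0, 8.5), 3.0, 1)  # pokes out the top
        f = edge_forces(vol, m, StageParameters(gradient_search_radius=4))
        assert np.all(np.isfinite(f))


class TestBalloonForce:
    def test_object_label_gives_unit_normal_force(self):
        classified = _uniform(value=1.0)
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        f = balloon_forces(classified, m, StageParameters())
        n = vertex_normals(m)
        assert np.allclose(f, n, atol=1e-12)

    def test_gel_label_gives_zero_force(self):
        classified = _uniform(value=-1.0)
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        f = balloon_forces(classified, m, StageParameters())
        assert np.abs(f).max() == 0.0

    def test_pass_band_is_exact(self):
        m = build_simplex_sphere((12, 12, 12), 3.0, 0)
        params = StageParameters()  # t_low=-0.99, t_high=1.0
        for value, active in [(-0.99, True), (-0.991, False), (1.0, True), (1.001, False)]:
            f = balloon_forces(_uniform(value=value), m, params)
            assert (np.abs(f).max() > 0) == active

    def test_indicator_invariant_to_in_band_rescaling(self):
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        params = StageParameters()
        f1 = balloon_forces(_uniform(value=0.2), m, params)
        f2 = balloon_forces(_uniform(value=0.9), m, params)
        assert np.allclose(f1, f2)

    def test_pure_balloon_inflates_strictly_monotonically(self):
        classified = _uniform(value=1.0)
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        params = StageParameters(w_balloon=0.08)
        c = np.array([12.0, 12.0, 12.0])
        prev = np.linalg.norm(m.vertices - c, axis=1).mean()
        for _ in range(20):
            f = params.w_balloon * balloon_forces(classified, m, params)
            step(m, f, params)
            cur = np.linalg.norm(m.vertices - c, axis=1).mean()
            assert cur > prev
            prev = cur

    def test_sphere_inflates_until_classified_ball_boundary(self):
        # classified ball of radius 8; balloon + smoothing only
        vol = _uniform((32, 32, 32), value=-1.0)
        gx, gy, gz = np.meshgrid(*[np.arange(32)] * 3, indexing="ij")
        ball = (gx - 15.5) ** 2 + (gy - 15.5) ** 2 + (gz - 15.5) ** 2 <= 8.0**2
        vol.values[ball] = 1.0
        m = build_simplex_sphere((15.5, 15.5, 15.5), 3.0, 1)
        params = StageParameters(w_balloon=0.08, w_internal=0.9)
        for _ in range(80):
            f = params.w_internal * internal_forces(m, params) + \
                params.w_balloon * balloon_forces(vol, m, params)
            step(m, f, params)
        radii = np.linalg.norm(m.vertices - 15.5, axis=1)
        assert 7.0 < radii.mean() < 9.5  # stopped at the ball boundary


class TestCollisionForce:
    def test_zero_outside_energy_support(self):
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        energy = BinaryMask(np.zeros((24, 24, 24), np.uint8), [1, 1, 1], [0, 0, 0])
        f = collision_forces(energy, _uniform(), m, StageParameters())
        assert np.abs(f).max() == 0.0

    def test_active_only_at_gated_vertices(self):
        vol = _uniform()
        vol.values[:, :, 10] = 50.0  # some gradient structure
        from scipy.ndimage import gaussian_gradient_magnitude

        gm = vol.like(gaussian_gradient_magnitude(vol.values, 1.0))
        m = build_simplex_sphere((12, 12, 12), 3.0, 1)
        ev = np.zeros((24, 24, 24), np.uint8)
        ev[:, :, :12] = 1  # lower half is foreign territory
        energy = BinaryMask(ev, [1, 1, 1], [0, 0, 0])
        f = collision_forces(energy, gm, m, StageParameters())
        gated = m.vertices[:, 2] < 11.5
        assert np.abs(f[~gated]).max() == 0.0


class TestMotionUpdate:
    def test_stationary_with_zero_forces_and_no_history(self, unit_sphere1):
        m = unit_sphere1.copy()
        before = m.vertices.copy()
        step(m, np.zeros_like(m.vertices), StageParameters())
        assert np.array_equal(m.vertices, before)

    def test_gamma_one_removes_inertia(self, unit_sphere1):
        m = unit_sphere1.copy()
        m.prev_positions = m.vertices - 0.3  # fake history
        before = m.vertices.copy()
        step(m, np.zeros_like(m.vertices), StageParameters(gamma=1.0))
        assert np.array_equal(m.vertices, before)

    def test_single_force_with_gamma_one_displaces_exactly(self, unit_sphere1):
        m = unit_sphere1.copy()
        f = np.zeros_like(m.vertices)
        f[3] = [0.01, -0.02, 0.005]
        before = m.vertices.copy()
        step(m, f, StageParameters(gamma=1.0))
        assert np.allclose(m.vertices - before, f)

    def test_max_step_caps_displacement(self, unit_sphere1):
        m = unit_sphere1.copy()
        f = np.full_like(m.vertices, 10.0)
        before = m.vertices.copy()
        step(m, f, StageParameters(gamma=1.0), max_step=0.5)
        d = np.linalg.norm(m.vertices - before, axis=1)
        assert np.allclose(d, 0.5)

    def test_nonfinite_force_aborts_naming_vertex(self, unit_sphere1):
        m = unit_sphere1.copy()
        f = np.zeros_like(m.vertices)
        f[7, 1] = np.nan
        with pytest.raises(ForceError, match="vertex 7"):
            step(m, f, StageParameters())


class TestExternalForceDirection:
    def test_all_external_forces_parallel_to_normals(self, phantom4):
        _, volume, _, seeds, _ = phantom4
        from scipy.ndimage import gaussian_gradient_magnitude

        gm = volume.like(gaussian_gradient_magnitude(volume.values.astype(float), 1.0))
        classified = volume.like(np.where(volume.values > 70, 1.0, -1.0))
        m = build_simplex_sphere(seeds[0], 5.0, 1)
        params = StageParameters()
        n = vertex_normals(m)
        ev = np.zeros(volume.shape, np.uint8)
        ev[: volume.shape[0] // 2] = 1
        energy = BinaryMask.from_volume_grid(volume, ev)
        for f in (
            gradient_forces(gm, m, params),
            edge_forces(volume, m, params),
            balloon_forces(classified, m, params),
            collision_forces(energy, gm, m, params),
        ):
            cross = np.linalg.norm(np.cross(f, n), axis=1)
            mag = np.linalg.norm(f, axis=1)
            assert np.all(cross <= 1e-9 * np.maximum(mag, 1e-30))
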