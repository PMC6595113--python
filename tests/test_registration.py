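"""Triangle-matching registration vs the orthogonal-Procrustes oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cspine as cs
from cspine.registration import (
    fit_rigid_procrustes,
    fit_rigid_triangle,
    register_model_to_neutral,
)


def _random_triangle(rng, span=50.0):
    while True:
        tri = rng.uniform(-span, span, (3, 3))
        if 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) > 5.0:
            return tri


def _random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-100.0, 100.0, 3)
    return R, t


class TestTriangleFit:
    def test_identical_triangles_give_identity(self):
        tri = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        pose = fit_rigid_triangle(tri, tri)
        assert np.allclose(pose.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(pose.translation, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_apply_then_recover_random_transform(self, seed):
        rng = np.random.default_rng(seed)
        src = _random_triangle(rng)
        R, t = _random_rigid(rng)
        tgt = src @ R.T + t
        pose = fit_rigid_triangle(src, tgt)
        assert np.linalg.norm(pose.rotation - R) < 1e-9
        assert np.linalg.norm(pose.translation - t) < 1e-8
        assert np.linalg.norm(pose.apply(src) - tgt) < 1e-9

    def test_collinear_triangle_rejected_naming_vertices(self):
        bad = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        good = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        with pytest.raises(ValueError, match="source"):
            fit_rigid_triangle(bad, good)
        with pytest.raises(ValueError, match="target"):
            fit_rigid_triangle(good, bad)

    def test_similar_triangle_matches_vertex1_and_edge_direction(self):
        """No scaling is applied: vertex 1 maps exactly, the 1-2 edge
        direction matches, and the misfit lands on the far vertices."""
        rng = np.random.default_rng(3)
        src = _random_triangle(rng)
        R, t = _random_rigid(rng)
        tgt = (1.5 * src) @ R.T + t  # similar, not congruent
        pose = fit_rigid_triangle(src, tgt)
        mapped = pose.apply(src)
        assert np.linalg.norm(mapped[0] - tgt[0]) < 1e-9
        e_mapped = mapped[1] - mapped[0]
        e_tgt = tgt[1] - tgt[0]
        cos = e_mapped @ e_tgt / np.linalg.norm(e_mapped) / np.linalg.norm(e_tgt)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(mapped[2] - tgt[2]) > 1.0  # residual surfaced


class TestProcrustes:
    def test_identity_case(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        pose = fit_rigid_procrustes(pts, pts)
        assert np.allclose(pose.rotation, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_recovery_of_known_transform(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(-40, 40, (4, 3))
        R, t = _random_rigid(rng)
        pose = fit_rigid_procrustes(pts, pts @ R.T + t)
        assert np.linalg.norm(pose.rotation - R) < 1e-9
        assert np.linalg.norm(pose.translation - t) < 1e-8

    def test_noise_monte_carlo_rotation_error_bounded(self, model):
        """sigma = 0.1 mm marker noise on a real marker cluster keeps the
        rotation error below half a degree in every seeded trial."""
        local = model.vertebrae[cs.Vertebra.C0].marker_array()
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            R, t = _random_rigid(rng)
            noisy = local @ R.T + t + rng.normal(0, 0.1, local.shape)
            pose = fit_rigid_procrustes(local, noisy)
            err = Rotation.from_matrix(pose.rotation.T @ R).magnitude()
            worst = max(worst, np.degrees(err))
        assert worst <= 0.5

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_procrustes(line, line)

    def test_reflection_guard_returns_proper_rotation(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(-10, 10, (4, 3))
        tgt = src.copy()
        tgt[:, 0] *= -1  # mirrored cloud
        pose = fit_rigid_procrustes(src, tgt)
        assert np.linalg.det(pose.rotation) == pytest.approx(1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_equals_procrustes_for_congruent_triangles(self, seed):
        rng = np.random.default_rng(900 + seed)
        for _ in range(100):
            src = _random_triangle(rng)
            R, t = _random_rigid(rng)
            tgt = src @ R.T + t
            a = fit_rigid_triangle(src, tgt)
            b = fit_rigid_procrustes(src, tgt)
            assert np.linalg.norm(a.rotation - b.rotation) <= 1e-6
            assert np.linalg.norm(a.translation - b.translation) <= 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_left_invariance_under_common_rigid_motion(self, seed):
        """Pre-transforming source and target by the same rigid motion
        conjugates the recovered pose and preserves the residual."""
        rng = np.random.default_rng(40 + seed)
        src = _random_triangle(rng)
        R, t = _random_rigid(rng)
        tgt = src @ R.T + t + rng.normal(0, 0.5, src.shape)  # non-congruent
        G, g = _random_rigid(rng)
        pose = fit_rigid_triangle(src, tgt)
        pose_moved = fit_rigid_triangle(src @ G.T + g, tgt @ G.T + g)
        res = np.linalg.norm(pose.apply(src) - tgt, axis=1)
        res_moved = np.linalg.norm(
            pose_moved.apply(src @ G.T + g) - (tgt @ G.T + g), axis=1
        )
        assert np.allclose(res, res_moved, atol=1e-8)


class TestRegisterModelToNeutral:
    def test_self_generated_neutral_registers_exactly(self, model, phys_capture):
        traj, _ = phys_capture
        result = register_model_to_neutral(model, traj.frame_markers(0))
        for v, rms in result.rms_residuals_mm.items():
            assert rms <= 1e-9, v

    def test_noise_keeps_residual_below_half_mm(self, model):
        sc = cs.ScenarioConfig.physiological(noise_sigma=0.1, n_frames=10, seed=4)
        traj, _ = cs.generate_trajectory(model, sc)
        result = register_model_to_neutral(model, traj.frame_markers(0))
        assert all(r <= 0.5 for r in result.rms_residuals_mm.values())

    def test_missing_marker_falls_back_to_remaining_triangle(self, model,
                                                             phys_capture):
        traj, _ = phys_capture
        markers = traj.frame_markers(0)
        del markers[(cs.Vertebra.C1, "c1_ant")]
        result = register_model_to_neutral(model, markers)
        assert result.rms_residuals_mm[cs.Vertebra.C1] <= 1e-9

    def test_too_few_markers_error_names_vertebra(self, model, phys_capture):
        traj, _ = phys_capture
        markers = {
            k: v for k, v in traj.frame_markers(0).items()
            if k[0] != cs.Vertebra.C2 or k[1] == "c2_spin"
        }
        with pytest.raises(ValueError, match="C2"):
            register_model_to_neutral(model, markers)

    def test_isometry_preserved_by_registered_pose(self, model, phys_capture):
        traj, _ = phys_capture
        result = register_model_to_neutral(model, traj.frame_markers(0))
        geo = model.vertebrae[cs.Vertebra.C0]
        pts = geo.marker_array()
        moved = result.poses[cs.Vertebra.C0].apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_high_residual_warns(self, model, phys_capture):
        traj, _ = phys_capture
        markers = dict(traj.frame_markers(0))
        key = (cs.Vertebra.C3, "base_ant_left")
        markers[key] = markers[key] + np.array([4.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="C3"):
            register_model_to_neutral(model, markers, method="procrustes")
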