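"""Pose series, relative sagittal angles, ROM and instability criterion."""

import numpy as np
import pytest

import cspine as cs
from cspine.kinematics import (
    JointAngleSeries,
    classify_instability,
    pose_series,
    relative_angle,
    rom_summary,
)
from cspine.mocap import pose_stack_from_angles


def _series(theta, joint=cs.Joint.C0C1, missing=None):
    theta = np.asarray(theta, dtype=float)
    return JointAngleSeries(
        joint=joint,
        theta_deg=theta,
        ap_translation_mm=np.zeros_like(theta),
        missing=np.zeros(theta.shape, bool) if missing is None else missing,
        rate_hz=500.0,
    )


class TestPoseSeries:
    def test_static_trajectory_gives_constant_pose(self, model):
        rom = {k: 0.0 for k in cs.PHYSIOLOGICAL_ROM}
        sc = cs.ScenarioConfig(rom_per_joint=rom, noise_sigma=0.0, n_frames=20)
        traj, _ = cs.generate_trajectory(model, sc)
        ps = pose_series(traj, model, cs.Vertebra.C1)
        assert not ps.missing.any()
        assert np.allclose(ps.rotations, np.eye(3), atol=1e-9)

    def test_prescribed_rotation_recovered_to_machine_precision(self, model):
        angles = {j: np.array([0.0, 10.0]) for j in [cs.Joint.C0C1]}
        angles[cs.Joint.C1C2] = np.zeros(2)
        angles[cs.Joint.C2C3] = np.zeros(2)
        poses = pose_stack_from_angles(model, angles)
        upper, lower = poses[cs.Vertebra.C0][1], poses[cs.Vertebra.C1][1]
        R_rel = lower.rotation.T @ upper.rotation
        theta = np.degrees(np.arctan2(R_rel[0, 2], R_rel[0, 0]))
        assert theta == pytest.approx(10.0, abs=1e-9)

    def test_frames_with_all_markers_missing_are_flagged_not_dropped(
        self, model, phys_capture
    ):
        traj, _ = phys_capture
        idx = traj.marker_indices(cs.Vertebra.C2)
        missing = traj.missing.copy()
        missing[100, idx] = True
        pos = traj.positions.copy()
        pos[100, idx] = np.nan
        broken = cs.MarkerTrajectory(
            rate_hz=traj.rate_hz, labels=traj.labels, positions=pos, missing=missing
        )
        ps = pose_series(broken, model, cs.Vertebra.C2)
        assert ps.missing[100]
        assert not ps.missing[99] and not ps.missing[101]
        assert np.isfinite(ps.rotations[99]).all()

    def test_partial_occlusion_still_fits_from_three_markers(self, model,
                                                             phys_capture):
        traj, _ = phys_capture
        idx = traj.marker_indices(cs.Vertebra.C0)[0]
        missing = traj.missing.copy()
        missing[:, idx] = True
        pos = traj.positions.copy()
        pos[:, idx] = np.nan
        occluded = cs.MarkerTrajectory(
            rate_hz=traj.rate_hz, labels=traj.labels, positions=pos, missing=missing
        )
        full = pose_series(traj, model, cs.Vertebra.C0)
        part = pose_series(occluded, model, cs.Vertebra.C0)
        assert not part.missing.any()
        assert np.allclose(full.rotations, part.rotations, atol=1e-9)

    def test_vertebra_absent_from_trajectory_raises(self, model, phys_capture):
        traj, _ = phys_capture
        keep = [i for i, (v, _) in enumerate(traj.labels) if v != cs.Vertebra.C3]
        reduced = cs.MarkerTrajectory(
            rate_hz=traj.rate_hz,
            labels=[traj.labels[i] for i in keep],
            positions=traj.positions[:, keep],
            missing=traj.missing[:, keep],
        )
        with pytest.raises(ValueError, match="C3"):
            pose_series(reduced, model, cs.Vertebra.C3)


class TestRelativeAngle:
    def test_identical_motion_gives_zero_series(self, model, phys_capture):
        traj, _ = phys_capture
        ps = pose_series(traj, model, cs.Vertebra.C1)
        s = relative_angle(ps, ps, cs.Joint.C0C1, model)
        assert np.allclose(s.theta_deg, 0.0, atol=1e-10)
        assert np.allclose(s.ap_translation_mm, 0.0, atol=1e-10)

    @pytest.mark.parametrize(
        "capture, joint, direction, expected",
        [
            ("phys_capture", cs.Joint.C1C2, cs.Direction.FLEXION, 8.84),
            ("phys_capture", cs.Joint.C0C1, cs.Direction.EXTENSION, 11.16),
            ("inst_capture", cs.Joint.C1C2, cs.Direction.FLEXION, 13.70),
            ("inst_capture", cs.Joint.C1C2, cs.Direction.EXTENSION, 17.20),
        ],
    )
    def test_prescribed_end_ranges_recovered(self, model, request, capture,
                                             joint, direction, expected):
        traj, _ = request.getfixturevalue(capture)
        upper = pose_series(traj, model, joint.upper)
        lower = pose_series(traj, model, joint.lower)
        s = relative_angle(upper, lower, joint, model)
        got = s.theta_deg.max() if direction is cs.Direction.FLEXION else -s.theta_deg.min()
        assert got == pytest.approx(expected, abs=0.01)

    def test_frame_count_mismatch_rejected(self, model, phys_capture):
        traj, _ = phys_capture
        a = pose_series(traj, model, cs.Vertebra.C0)
        b = pose_series(traj, model, cs.Vertebra.C1)
        b.rotations = b.rotations[:-1]
        b.translations = b.translations[:-1]
        b.missing = b.missing[:-1]
        with pytest.raises(ValueError, match="frame counts"):
            relative_angle(a, b, cs.Joint.C0C1, model)

    def test_small_angle_additivity_across_two_joints(self, model):
        """theta1 at C0-C1 plus theta2 at C1-C2 compose to theta1+theta2
        between C0 and C2 for sagittal-plane motion."""
        rom = {k: 0.0 for k in cs.PHYSIOLOGICAL_ROM}
        rom[(cs.Joint.C0C1, cs.Direction.FLEXION)] = 7.0
        rom[(cs.Joint.C1C2, cs.Direction.FLEXION)] = 15.0
        sc = cs.ScenarioConfig(rom_per_joint=rom, noise_sigma=0.0, n_frames=101)
        traj, _ = cs.generate_trajectory(model, sc)
        c0 = pose_series(traj, model, cs.Vertebra.C0)
        c2 = pose_series(traj, model, cs.Vertebra.C2)
        s = relative_angle(c0, c2, cs.Joint.C1C2, model)
        assert s.theta_deg.max() == pytest.approx(22.0, abs=0.1)


class TestRomSummary:
    def test_monotone_ramp_to_positive_value(self):
        s = _series(np.linspace(0.0, 5.51, 100))
        rom = rom_summary([s])
        assert rom.flexion_deg[cs.Joint.C0C1] == pytest.approx(5.51)
        assert rom.extension_deg[cs.Joint.C0C1] == 0.0

    def test_constant_zero_series(self):
        rom = rom_summary([_series(np.zeros(10))])
        assert rom.flexion_deg[cs.Joint.C0C1] == 0.0
        assert rom.extension_deg[cs.Joint.C0C1] == 0.0

    def test_sign_convention_on_mixed_series(self):
        rom = rom_summary([_series([0.0, 3.2, -11.16, 1.0])])
        assert rom.flexion_deg[cs.Joint.C0C1] == pytest.approx(3.2)
        assert rom.extension_deg[cs.Joint.C0C1] == pytest.approx(11.16)

    def test_time_reversal_invariance(self):
        theta = np.sin(np.linspace(0, 2 * np.pi, 77)) * 9.0
        a = rom_summary([_series(theta)])
        b = rom_summary([_series(theta[::-1])])
        assert a.flexion_deg == b.flexion_deg
        assert a.extension_deg == b.extension_deg

    def test_missing_frames_excluded_from_extrema(self):
        theta = np.array([0.0, 50.0, 2.0])
        missing = np.array([False, True, False])
        rom = rom_summary([_series(theta, missing=missing)])
        assert rom.flexion_deg[cs.Joint.C0C1] == pytest.approx(2.0)

    def test_all_missing_series_rejected(self):
        with pytest.raises(ValueError, match="all frames missing"):
            rom_summary([_series([1.0, 2.0], missing=np.array([True, True]))])


class TestClassifyInstability:
    @pytest.mark.parametrize(
        "angle, disp, expected",
        [
            (13.70, 0.0, True),   # angle branch
            (11.0, 3.5, False),   # strict boundary
            (0.0, 3.6, True),     # displacement branch
            (8.84, 0.0, False),
            (10.999, 3.499, False),
            (11.001, 0.0, True),
        ],
    )
    def test_strict_threshold_logic(self, angle, disp, expected):
        assert classify_instability(angle, disp) is expected

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_instability(float("nan"), 0.0)


class TestFullPipelineRoundTrip:
    def test_noise_free_recovery_of_all_prescribed_end_ranges(
        self, model, phys_capture, inst_capture
    ):
        for capture, rom_table in (
            (phys_capture, cs.PHYSIOLOGICAL_ROM),
            (inst_capture, cs.INSTABILITY_ROM),
        ):
            traj, _ = capture
            res = cs.analyze_trajectory(traj, model)
            for (joint, direction), expected in rom_table.items():
                got = (
                    res.rom.flexion_deg[joint]
                    if direction is cs.Direction.FLEXION
                    else res.rom.extension_deg[joint]
                )
                assert got == pytest.approx(expected, abs=0.01)

    def test_noisy_recovery_within_half_degree(self, model):
        sc = cs.ScenarioConfig.physiological(noise_sigma=0.2, seed=77)
        traj, _ = cs.generate_trajectory(model, sc)
        res = cs.analyze_trajectory(traj, model, smooth_cutoff_hz=6.0)
        for (joint, direction), expected in cs.PHYSIOLOGICAL_ROM.items():
            if expected == 0.0:
                continue
            got = (
                res.rom.flexion_deg[joint]
                if direction is cs.Direction.FLEXION
                else res.rom.extension_deg[joint]
            )
            assert got == pytest.approx(expected, abs=0.5)
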