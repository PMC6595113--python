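"""End-to-end analysis: register → pose series → joint angles → ROM →
instability classification → ligament state.

Thin orchestration over the stage modules, shared by the command-line
interface, the acceptance script and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import (
    JointAngleSeries,
    RomSummary,
    classify_instability,
    pose_series,
    relative_angle,
    rom_summary,
)
from .ligaments import LigamentStateRow, build_state_table
from .model import (
    Condition,
    Direction,
    InstabilityCriterion,
    Joint,
    SpineModel,
    Vertebra,
)
from .mocap import MarkerTrajectory
from .registration import RegistrationResult, register_model_to_neutral

__all__ = ["AnalysisResult", "analyze_trajectory", "end_range_ligament_state"]

_VERTEBRAE = (Vertebra.C0, Vertebra.C1, Vertebra.C2, Vertebra.C3)

_JOINT_PAIRS = {
    Joint.C0C1: (Vertebra.C0, Vertebra.C1),
    Joint.C1C2: (Vertebra.C1, Vertebra.C2),
    Joint.C2C3: (Vertebra.C2, Vertebra.C3),
}


@dataclass
class AnalysisResult:
    """Outcome of one trajectory analysis.

    ``unstable`` is the headline per-joint radiographic classification,
    assessed on the flexion end range: physiological extension of the
    upper cervical joints already exceeds the 11° subaxial threshold
    (the standard does not transfer to extension at these levels), so
    the angle branch of the criterion is evaluated on the flexion film.
    ``unstable_by_direction`` carries the raw per-direction application
    of the criterion for completeness.
    """

    registration: RegistrationResult
    angle_series: dict[Joint, JointAngleSeries]
    rom: RomSummary
    unstable: dict[Joint, bool]
    unstable_by_direction: dict[tuple[Joint, Direction], bool]
    max_ap_displacement_mm: dict[Joint, float]


def analyze_trajectory(
    traj: MarkerTrajectory,
    model: SpineModel,
    criterion: InstabilityCriterion | None = None,
    smooth_cutoff_hz: float | None = None,
    registration_method: str = "triangle",
    condition: str | None = None,
) -> AnalysisResult:
    """Full kinematic analysis of a marker trajectory.

    The neutral (first) frame registers the model; every frame is then
    pose-fitted per vertebra, relative sagittal angles and AP
    translations are extracted per joint, and each joint is classified
    against the radiographic instability criterion (flexion end range
    and peak AP displacement; see :class:`AnalysisResult`).
    """
    registration = register_model_to_neutral(
        model, traj.frame_markers(0), method=registration_method
    )
    poses = {
        v: pose_series(traj, model, v, smooth_cutoff_hz=smooth_cutoff_hz)
        for v in _VERTEBRAE
    }
    series: dict[Joint, JointAngleSeries] = {}
    for joint, (upper, lower) in _JOINT_PAIRS.items():
        series[joint] = relative_angle(
            poses[upper], poses[lower], joint, model, rate_hz=traj.rate_hz
        )
    rom = rom_summary(list(series.values()), condition=condition)
    unstable: dict[Joint, bool] = {}
    by_direction: dict[tuple[Joint, Direction], bool] = {}
    max_ap: dict[Joint, float] = {}
    for joint, s in series.items():
        valid = ~s.missing
        peak_ap = float(np.max(np.abs(s.ap_translation_mm[valid])))
        max_ap[joint] = peak_ap
        by_direction[(joint, Direction.FLEXION)] = classify_instability(
            rom.flexion_deg[joint], peak_ap, criterion
        )
        by_direction[(joint, Direction.EXTENSION)] = classify_instability(
            rom.extension_deg[joint], peak_ap, criterion
        )
        unstable[joint] = by_direction[(joint, Direction.FLEXION)]
    return AnalysisResult(
        registration=registration,
        angle_series=series,
        rom=rom,
        unstable=unstable,
        unstable_by_direction=by_direction,
        max_ap_displacement_mm=max_ap,
    )


def end_range_ligament_state(
    traj: MarkerTrajectory,
    model: SpineModel,
    condition: Condition,
    direction: Direction,
    smooth_cutoff_hz: float | None = None,
) -> list[LigamentStateRow]:
    """Ligament state table at the end-range frame of one movement.

    The end-range frame is the one maximizing (flexion) or minimizing
    (extension) the summed sagittal angle; length changes are measured
    between deformed attachment points there.
    """
    poses = {
        v: pose_series(traj, model, v, smooth_cutoff_hz=smooth_cutoff_hz)
        for v in _VERTEBRAE
    }
    series = {
        joint: relative_angle(poses[u], poses[l], joint, model, rate_hz=traj.rate_hz)
        for joint, (u, l) in _JOINT_PAIRS.items()
    }
    total = sum(np.nan_to_num(s.theta_deg) for s in series.values())
    frame = int(np.argmax(total) if direction is Direction.FLEXION else np.argmin(total))
    dl: dict[str, float] = {}
    for spec in model.ligaments:
        po = poses[spec.origin[0]].pose(frame)
        pi = poses[spec.insertion[0]].pose(frame)
        p0 = po.apply(model.attachment_world(*spec.origin))
        p1 = pi.apply(model.attachment_world(*spec.insertion))
        dl[spec.name] = float(np.linalg.norm(p1 - p0)) - spec.rest_length_L0
    return build_state_table(dl, model.ligaments, condition, direction)
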