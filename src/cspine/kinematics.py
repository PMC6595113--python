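"""Per-frame vertebra poses, relative joint angles, ROM and instability.

The pipeline stage after registration: least-squares (Kabsch) fits of each
vertebra's local marker cluster to the observed markers give per-frame
rigid poses; relative poses between adjacent vertebrae yield the signed
sagittal joint angle (flexion positive, extracted by projecting the
axis-angle vector of the relative rotation onto the lower vertebra's
medio-lateral axis) and the anterior-posterior translation of the upper
body's origin in the lower body's frame (reported as displacement from
the neutral first frame).  End-range extrema summarize the range of
motion, and the radiographic 11°/3.5 mm criterion classifies instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .model import InstabilityCriterion, Joint, SpineModel, Vertebra
from .mocap import MarkerTrajectory
from .pose import RigidPose

__all__ = [
    "PoseSeries",
    "JointAngleSeries",
    "RomSummary",
    "pose_series",
    "relative_angle",
    "rom_summary",
    "classify_instability",
]


@dataclass
class PoseSeries:
    """Per-frame rigid poses of one vertebra (local frame -> laboratory)."""

    vertebra: Vertebra
    rotations: np.ndarray  # (T, 3, 3)
    translations: np.ndarray  # (T, 3)
    missing: np.ndarray  # (T,) frames with < 3 visible markers

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    def pose(self, frame: int) -> RigidPose:
        if self.missing[frame]:
            raise ValueError(f"frame {frame} has no pose (markers missing)")
        return RigidPose(self.rotations[frame], self.translations[frame])


@dataclass
class JointAngleSeries:
    """Signed sagittal angle (deg, flexion positive) and AP translation (mm).

    ``ap_translation_mm`` is the anterior (+X of the lower body frame)
    displacement of the upper body's origin relative to its neutral
    (first valid frame) value.  Frames without a pose on either side are
    flagged missing, never dropped silently.
    """

    joint: Joint
    theta_deg: np.ndarray
    ap_translation_mm: np.ndarray
    missing: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        valid = self.theta_deg[~self.missing]
        if valid.size and np.max(np.abs(valid)) > 90.0:
            raise ValueError("sagittal angles above 90 deg are non-physiological")


@dataclass
class RomSummary:
    """End-range angles per joint: flexion and extension extrema (deg)."""

    flexion_deg: dict[Joint, float]
    extension_deg: dict[Joint, float]
    condition: str | None = None

    def as_rows(self) -> list[dict]:
        rows = []
        for movement, table in (
            ("Flexion", self.flexion_deg),
            ("Extension", self.extension_deg),
        ):
            for joint, angle in table.items():
                rows.append(
                    {"Movements": movement, "Segment": joint.value, "angle_deg": angle}
                )
        return rows


def _lowpass(positions: np.ndarray, missing: np.ndarray, rate_hz: float,
             cutoff_hz: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass on marker coordinates.

    Only applied to markers with no missing frames; occluded channels are
    left untouched (no silent interpolation).
    """
    b, a = signal.butter(4, cutoff_hz / (rate_hz / 2.0))
    out = positions.copy()
    for m in range(positions.shape[1]):
        if not missing[:, m].any():
            out[:, m, :] = signal.filtfilt(b, a, positions[:, m, :], axis=0)
    return out


def pose_series(
    traj: MarkerTrajectory,
    model: SpineModel,
    vertebra: Vertebra,
    smooth_cutoff_hz: float | None = None,
) -> PoseSeries:
    """Per-frame Procrustes fit of a vertebra's marker cluster.

    Frames where fewer than 3 of the vertebra's markers are visible are
    flagged missing.  When ``smooth_cutoff_hz`` is given, a zero-phase
    low-pass is applied to the marker positions first (quasi-static motion
    keeps end ranges intact; 6 Hz is a sensible cutoff for 500-Hz data).

    Raises
    ------
    ValueError
        If the vertebra has no markers in the trajectory.
    """
    geo = model.vertebrae[vertebra]
    idx = traj.marker_indices(vertebra)
    if not idx:
        raise ValueError(f"vertebra {vertebra.value} absent from trajectory")
    cols = {traj.labels[i][1]: i for i in idx}
    labels = [lb for lb in geo.marker_labels if lb in cols]
    if len(labels) < 3:
        raise ValueError(
            f"vertebra {vertebra.value}: trajectory carries only "
            f"{len(labels)} of its markers"
        )
    order = [cols[lb] for lb in labels]
    local = np.array([geo.markers_local[lb] for lb in labels])  # (m, 3)

    positions = traj.positions
    if smooth_cutoff_hz is not None:
        positions = _lowpass(positions, traj.missing, traj.rate_hz, smooth_cutoff_hz)
    obs = positions[:, order, :]  # (T, m, 3)
    miss = traj.missing[:, order]  # (T, m)

    T, m = obs.shape[0], obs.shape[1]
    rotations = np.full((T, 3, 3), np.nan)
    translations = np.full((T, 3), np.nan)
    frame_missing = miss.sum(axis=1) > m - 3

    complete = ~miss.any(axis=1)
    if complete.any():
        # Batched Kabsch over all fully-visible frames.
        mu_s = local.mean(axis=0)
        sc = local - mu_s  # (m, 3)
        Y = obs[complete]  # (F, m, 3)
        mu_t = Y.mean(axis=1)  # (F, 3)
        tc = Y - mu_t[:, None, :]
        H = np.einsum("mi,fmj->fij", sc, tc)  # (F, 3, 3)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(np.transpose(Vt, (0, 2, 1)) @
                                  np.transpose(U, (0, 2, 1))))
        D = np.zeros_like(H)
        D[:, 0, 0] = 1.0
        D[:, 1, 1] = 1.0
        D[:, 2, 2] = d
        R = np.transpose(Vt, (0, 2, 1)) @ D @ np.transpose(U, (0, 2, 1))
        rotations[complete] = R
        translations[complete] = mu_t - np.einsum("fij,j->fi", R, mu_s)

    # Partially-occluded frames: per-frame fit on the visible subset.
    partial = ~complete & ~frame_missing
    for f in np.nonzero(partial)[0]:
        vis = ~miss[f]
        from .registration import fit_rigid_procrustes

        pose = fit_rigid_procrustes(local[vis], obs[f, vis])
        rotations[f] = pose.rotation
        translations[f] = pose.translation

    return PoseSeries(
        vertebra=vertebra,
        rotations=rotations,
        translations=translations,
        missing=frame_missing,
    )


def _rotvec_from_matrices(R: np.ndarray) -> np.ndarray:
    """Axis-angle (rotation vector) of a stack of rotation matrices."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(R).as_rotvec()


def relative_angle(
    upper: PoseSeries,
    lower: PoseSeries,
    joint: Joint,
    model: SpineModel,
    rate_hz: float = 500.0,
) -> JointAngleSeries:
    """Signed sagittal angle and AP translation of upper relative to lower.

    Per frame: R_rel = R_lowerᵀ R_upper; theta is the component of its
    rotation vector along the lower body's medio-lateral axis (degrees,
    flexion positive).  Translation is the anterior component of the upper
    origin expressed in the lower frame, relative to the neutral first
    valid frame.

    Raises
    ------
    ValueError
        On frame-count mismatch.
    """
    if upper.n_frames != lower.n_frames:
        raise ValueError("pose series frame counts differ")
    missing = upper.missing | lower.missing
    T = upper.n_frames
    theta = np.full(T, np.nan)
    ap = np.full(T, np.nan)
    ok = ~missing
    if ok.any():
        Rl = lower.rotations[ok]
        Ru = upper.rotations[ok]
        R_rel = np.transpose(Rl, (0, 2, 1)) @ Ru
        rotvec = _rotvec_from_matrices(R_rel)
        axis = model.vertebrae[joint.lower].sagittal_reference_axis
        theta[ok] = np.degrees(rotvec @ axis)
        d = np.einsum(
            "fij,fi->fj", Rl, (upper.translations[ok] - lower.translations[ok])
        )
        anterior = np.array([1.0, 0.0, 0.0])
        ap[ok] = d @ anterior
        ap[ok] -= ap[ok][0]  # displacement from the neutral first valid frame
    return JointAngleSeries(
        joint=joint,
        theta_deg=theta,
        ap_translation_mm=ap,
        missing=missing,
        rate_hz=rate_hz,
    )


def rom_summary(
    series: list[JointAngleSeries], condition: str | None = None
) -> RomSummary:
    """End-range extrema: flexion = max positive theta, extension = |min|.

    Missing frames are excluded from the extrema; an all-missing series is
    an error.
    """
    flex: dict[Joint, float] = {}
    ext: dict[Joint, float] = {}
    for s in series:
        valid = s.theta_deg[~s.missing]
        if valid.size == 0:
            raise ValueError(f"joint {s.joint.value}: all frames missing")
        flex[s.joint] = float(max(valid.max(), 0.0))
        ext[s.joint] = float(max(-valid.min(), 0.0))
    return RomSummary(flexion_deg=flex, extension_deg=ext, condition=condition)


def classify_instability(
    angle_deg: float,
    displacement_mm: float,
    criterion: InstabilityCriterion | None = None,
) -> bool:
    """Radiographic instability: angle > 11° OR displacement > 3.5 mm.

    Strict inequalities — boundary values classify stable.
    """
    if criterion is None:
        criterion = InstabilityCriterion()
    if not (np.isfinite(angle_deg) and np.isfinite(displacement_mm)):
        raise ValueError("inputs must be finite")
    return (
        angle_deg > criterion.angle_threshold_deg
        or displacement_mm > criterion.displacement_threshold_mm
    )
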