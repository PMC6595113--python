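"""Synthetic marker-trajectory generation with known ground truth.

Emulates the in vitro protocol this package is built around: a cadaveric
C0–C3 complex cast on a fixed base, four screw-mounted reflective markers
per vertebra, 500-Hz optical capture, and slow (quasi-static) sagittal
flexion/extension driven to the end ranges of motion of each joint.  The
generator prescribes smooth per-joint sagittal rotations, composes rigid
poses bottom-up from the fixed C3 base, and emits marker positions with
optional i.i.d. Gaussian noise and marker dropout.  The exact prescribed
joint-angle series is returned alongside, so every downstream stage can be
tested against ground truth.

Two study conditions are parameterized by their end-range angles
(degrees, atlanto-occipital C0–C1 and atlanto-axial C1–C2):

===============  ========  =========  =========  =========
condition        C0–C1 fl  C0–C1 ext  C1–C2 fl   C1–C2 ext
===============  ========  =========  =========  =========
physiological      3.49      11.16      8.84       14.20
instability        5.51      12.96      13.70      17.20
===============  ========  =========  =========  =========

Ligament fatigue (the instability induction) is additionally encoded as a
``stiffness_scale`` < 1 consumed by the equilibrium module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import Condition, Direction, Joint, SpineModel, Vertebra
from .pose import RigidPose

__all__ = [
    "ScenarioConfig",
    "MarkerTrajectory",
    "generate_trajectory",
    "apply_dropout",
    "PHYSIOLOGICAL_ROM",
    "INSTABILITY_ROM",
]

#: End-range sagittal angles (deg) per joint and direction, by condition.
PHYSIOLOGICAL_ROM: dict[tuple[Joint, Direction], float] = {
    (Joint.C0C1, Direction.FLEXION): 3.49,
    (Joint.C0C1, Direction.EXTENSION): 11.16,
    (Joint.C1C2, Direction.FLEXION): 8.84,
    (Joint.C1C2, Direction.EXTENSION): 14.20,
    (Joint.C2C3, Direction.FLEXION): 0.0,
    (Joint.C2C3, Direction.EXTENSION): 0.0,
}

INSTABILITY_ROM: dict[tuple[Joint, Direction], float] = {
    (Joint.C0C1, Direction.FLEXION): 5.51,
    (Joint.C0C1, Direction.EXTENSION): 12.96,
    (Joint.C1C2, Direction.FLEXION): 13.70,
    (Joint.C1C2, Direction.EXTENSION): 17.20,
    (Joint.C2C3, Direction.FLEXION): 0.0,
    (Joint.C2C3, Direction.EXTENSION): 0.0,
}


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic capture run.

    ``rom_per_joint`` maps (joint, direction) to the end-range angle in
    degrees; omitted joints stay at zero.  ``motion_profile`` selects the
    neutral→flexion→neutral→extension→neutral cycle shape
    ("sinusoidal_ramp": raised-cosine half-period ramps, zero velocity at
    neutral and end range; "linear_ramp": triangular).  ``noise_sigma`` is
    the marker noise standard deviation in mm (0.1 mm default, typical
    optical mocap precision); ``stiffness_scale`` (< 1 under instability)
    encodes ligament fatigue for the equilibrium module.
    """

    condition: Condition = Condition.PHYSIOLOGICAL
    rom_per_joint: dict[tuple[Joint, Direction], float] = field(default_factory=dict)
    motion_profile: str = "sinusoidal_ramp"
    duration_s: float = 2.4
    rate_hz: float = 500.0
    n_frames: int = 1200
    noise_sigma: float = 0.1
    dropout_prob: float = 0.0
    seed: int = 0
    stiffness_scale: float = 1.0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if not self.rom_per_joint:
            self.rom_per_joint = dict(
                PHYSIOLOGICAL_ROM
                if self.condition is Condition.PHYSIOLOGICAL
                else INSTABILITY_ROM
            )
        for key, v in self.rom_per_joint.items():
            if v < 0:
                raise ValueError(f"ROM must be non-negative, got {v} for {key}")
            if v > 90:
                raise ValueError(f"ROM {v} deg for {key} is non-physiological (> 90)")
        if self.motion_profile not in ("sinusoidal_ramp", "linear_ramp"):
            raise ValueError(f"unknown motion profile {self.motion_profile!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        if self.rate_hz <= 0 or self.duration_s <= 0 or self.n_frames < 2:
            raise ValueError("invalid sampling configuration")
        if self.stiffness_scale <= 0:
            raise ValueError("stiffness scale must be positive")

    def rom(self, joint: Joint, direction: Direction) -> float:
        return self.rom_per_joint.get((joint, direction), 0.0)

    @classmethod
    def physiological(cls, **kw) -> "ScenarioConfig":
        return cls(condition=Condition.PHYSIOLOGICAL, **kw)

    @classmethod
    def instability(cls, **kw) -> "ScenarioConfig":
        kw.setdefault("stiffness_scale", 0.5)
        return cls(condition=Condition.INSTABILITY, **kw)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["condition"] = self.condition.value
        d["rom_per_joint"] = {
            f"{j.value}:{dr.value}": v for (j, dr), v in self.rom_per_joint.items()
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "ScenarioConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        d = dict(d)
        if "rom_per_joint" in d:
            rom = {}
            for key, v in d["rom_per_joint"].items():
                j, dr = key.split(":")
                rom[(Joint(j), Direction(dr))] = float(v)
            d["rom_per_joint"] = rom
        return cls(**d)


@dataclass
class MarkerTrajectory:
    """Time-stamped laboratory-frame marker positions (the Vicon-like record).

    ``positions`` is (n_frames, n_markers, 3) in mm; ``missing`` flags
    occluded frame-markers (their positions are NaN).  ``labels`` pairs each
    column with its (vertebra, marker label).
    """

    rate_hz: float
    labels: list[tuple[Vertebra, str]]
    positions: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        T, M, three = self.positions.shape
        if three != 3 or M != len(self.labels):
            raise ValueError("positions shape inconsistent with labels")
        if self.missing.shape != (T, M):
            raise ValueError("missing mask shape mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")
        if not np.all(np.isfinite(self.positions[~self.missing])):
            raise ValueError("non-missing positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_hz

    def marker_indices(self, vertebra: Vertebra) -> list[int]:
        return [i for i, (v, _) in enumerate(self.labels) if v == vertebra]

    def frame_markers(self, frame: int) -> dict[tuple[Vertebra, str], np.ndarray]:
        """Visible markers of one frame, keyed by (vertebra, label)."""
        return {
            self.labels[m]: self.positions[frame, m]
            for m in range(self.n_markers)
            if not self.missing[frame, m]
        }


def motion_profile(config: ScenarioConfig) -> np.ndarray:
    """Normalized cycle phi(t) in [-1, 1]: 0 → +1 (flexion) → 0 → -1 → 0.

    The sinusoidal profile chains half-period raised-cosine ramps, giving
    zero angular velocity at neutral and at both end ranges — a
    quasi-static "slowly moving" drive.
    """
    t = np.arange(config.n_frames) / (config.n_frames - 1)  # 0..1
    if config.motion_profile == "sinusoidal_ramp":
        phi = np.where(
            t < 0.5,
            0.5 * (1 - np.cos(4 * np.pi * t)),
            -0.5 * (1 - np.cos(4 * np.pi * (t - 0.5))),
        )
    else:  # linear_ramp (triangular)
        phi = np.where(
            t < 0.5,
            1 - np.abs(4 * t - 1),
            -(1 - np.abs(4 * (t - 0.5) - 1)),
        )
    return phi


def _joint_angle_series(config: ScenarioConfig) -> dict[Joint, np.ndarray]:
    """Prescribed signed sagittal angle per joint per frame (deg)."""
    phi = motion_profile(config)
    series = {}
    for joint in Joint:
        flex = config.rom(joint, Direction.FLEXION)
        ext = config.rom(joint, Direction.EXTENSION)
        series[joint] = np.where(phi >= 0, flex * phi, ext * phi)
    return series


def _rotation_y(theta_rad: float) -> np.ndarray:
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def pose_stack_from_angles(
    model: SpineModel, angles_deg: dict[Joint, np.ndarray]
) -> dict[Vertebra, list[RigidPose]]:
    """Compose per-frame vertebra poses from prescribed joint angles.

    C3 stays at identity (fixed base).  Each upper vertebra rotates about
    the medio-lateral axis through its joint centre, composed on top of
    the lower vertebra's pose; poses map neutral laboratory coordinates to
    the current frame.
    """
    n = len(next(iter(angles_deg.values())))
    poses: dict[Vertebra, list[RigidPose]] = {
        Vertebra.C3: [RigidPose.identity() for _ in range(n)]
    }
    for joint in (Joint.C2C3, Joint.C1C2, Joint.C0C1):
        lower_poses = poses[joint.lower]
        center = model.joint_centers_world[joint]
        theta = np.deg2rad(angles_deg[joint])
        poses[joint.upper] = [
            lower_poses[i].compose(
                RigidPose.about_point(_rotation_y(theta[i]), center)
            )
            for i in range(n)
        ]
    return poses


def generate_trajectory(
    model: SpineModel, scenario: ScenarioConfig
) -> tuple[MarkerTrajectory, dict[Joint, np.ndarray]]:
    """Generate a synthetic capture plus its exact ground-truth angles.

    Returns
    -------
    (MarkerTrajectory, dict)
        The trajectory, and the prescribed signed sagittal angle series
        (deg, flexion positive) per joint — the ground truth that the
        kinematics pipeline should recover.

    Notes
    -----
    Identical seeds give identical output (all randomness flows through
    one ``numpy`` generator seeded with ``scenario.seed``).
    """
    labels: list[tuple[Vertebra, str]] = []
    local: list[np.ndarray] = []
    for vid in (Vertebra.C0, Vertebra.C1, Vertebra.C2, Vertebra.C3):
        geo = model.vertebrae[vid]
        for lb in geo.marker_labels:
            labels.append((vid, lb))
            local.append(geo.markers_local[lb] + geo.origin_world)
    if not labels:
        raise ValueError("model has no markers")
    neutral_world = np.array(local)  # (M, 3)

    angles = _joint_angle_series(scenario)
    poses = pose_stack_from_angles(model, angles)

    T, M = scenario.n_frames, len(labels)
    positions = np.empty((T, M, 3))
    for m, (vid, _) in enumerate(labels):
        vposes = poses[vid]
        for f in range(T):
            positions[f, m] = vposes[f].apply(neutral_world[m])

    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_sigma > 0:
        positions = positions + rng.normal(0.0, scenario.noise_sigma, positions.shape)

    traj = MarkerTrajectory(
        rate_hz=scenario.rate_hz,
        labels=labels,
        positions=positions,
        missing=np.zeros((T, M), dtype=bool),
    )
    if scenario.dropout_prob > 0:
        traj = apply_dropout(
            traj, scenario.dropout_prob, seed=int(rng.integers(2**31))
        )
    return traj, angles


def apply_dropout(
    traj: MarkerTrajectory, prob: float, seed: int
) -> MarkerTrajectory:
    """Flag each frame-marker missing independently with probability ``prob``.

    Surviving marker positions are unchanged; the same seed reproduces the
    same occlusion mask.
    """
    if not (0 <= prob < 1):
        raise ValueError("dropout probability must lie in [0, 1)")
    if prob == 0:
        return traj
    rng = np.random.default_rng(seed)
    mask = rng.random((traj.n_frames, traj.n_markers)) < prob
    missing = traj.missing | mask
    positions = traj.positions.copy()
    positions[missing] = np.nan
    return MarkerTrajectory(
        rate_hz=traj.rate_hz,
        labels=list(traj.labels),
        positions=positions,
        missing=missing,
    )
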