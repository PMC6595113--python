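"""Rigid-body poses (proper rotations + translations), mm."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidPose"]

_ORTHO_TOL = 1e-9


@dataclass
class RigidPose:
    """A proper rigid transform p -> R @ p + t.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1 (checked to
    1e-9); ``translation`` is in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3))
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (||R'R - I|| = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation must be proper (det = {det:.9f})")
        # Snap to the nearest rotation when within loose tolerance but
        # outside the strict one, so long compositions stay on SO(3).
        if err > _ORTHO_TOL:
            u, _, vt = np.linalg.svd(self.rotation)
            self.rotation = u @ vt

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def about_point(cls, rotation: np.ndarray, center: np.ndarray) -> "RigidPose":
        """Rotation about an axis through ``center`` (no net translation there)."""
        center = np.asarray(center, dtype=float)
        rotation = np.asarray(rotation, dtype=float)
        return cls(rotation=rotation, translation=center - rotation @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or a stack (n, 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidPose(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        rt = self.rotation.T
        return RigidPose(rotation=rt, translation=-rt @ self.translation)

    def to_json_dict(self) -> dict:
        return {
            "rotation_row_major": [float(x) for x in self.rotation.ravel()],
            "translation_mm": [float(x) for x in self.translation],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidPose":
        return cls(
            rotation=np.array(d["rotation_row_major"], dtype=float).reshape(3, 3),
            translation=np.array(d["translation_mm"], dtype=float),
        )
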