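"""Rigid registration of the geometric model onto observed markers.

Two routes are provided and cross-checked against each other:

* :func:`fit_rigid_triangle` — the constructive translate/spin procedure
  used to match a model marker triangle onto its experimental counterpart:
  translate vertex 1 onto vertex 1, spin about the normal through vertex 1
  to superimpose the 1–2 edge directions, then spin about that common edge
  to bring vertex 3 into the target plane on the correct side.
* :func:`fit_rigid_procrustes` — the weighted orthogonal-Procrustes
  (Kabsch) least-squares solution with a reflection guard, used as the
  independent oracle and for n > 3 markers.

For congruent noise-free triangles the two agree to numerical precision;
for merely similar triangles the triangle method matches vertex 1 and the
1–2 edge direction exactly and surfaces the vertex-3 residual (no scaling
is applied — downstream mechanics assumes rigid bodies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import SpineModel, Vertebra
from .pose import RigidPose

__all__ = [
    "fit_rigid_triangle",
    "fit_rigid_procrustes",
    "register_model_to_neutral",
    "RegistrationResult",
]

_DEGENERATE_AREA = 1e-6  # mm^2


def _check_triangle(points: np.ndarray, what: str) -> None:
    area = 0.5 * np.linalg.norm(
        np.cross(points[1] - points[0], points[2] - points[0])
    )
    if area <= _DEGENERATE_AREA:
        raise ValueError(
            f"degenerate (collinear) {what} triangle: vertices {points.tolist()}"
        )


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction u onto direction v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # Anti-parallel: rotate pi about any axis perpendicular to u.
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_angle(perp, np.pi)
    axis /= s
    return _axis_angle(axis, np.arctan2(s, c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def fit_rigid_triangle(source: np.ndarray, target: np.ndarray) -> RigidPose:
    """Constructive rigid fit of a source marker triangle onto a target.

    Parameters
    ----------
    source, target : (3, 3) arrays
        Vertex coordinates (mm), matched row by row.

    Returns
    -------
    RigidPose
        Pose mapping source vertices onto the target.  Vertex 1 maps
        exactly; for congruent triangles the residual RMS is at numerical
        precision, for similar triangles the vertex-3 misfit is left in
        the residual rather than absorbed by scaling.
    """
    src = np.asarray(source, dtype=float).reshape(3, 3)
    tgt = np.asarray(target, dtype=float).reshape(3, 3)
    _check_triangle(src, "source")
    _check_triangle(tgt, "target")

    # Step 1: translate source vertex 1 onto target vertex 1.
    # (carried implicitly: all rotations below act on vertex-1-relative
    # coordinates, and the final translation pins vertex 1.)
    u_edge = src[1] - src[0]
    v_edge = tgt[1] - tgt[0]

    # Step 2: spin about the axis through vertex 1 perpendicular to the
    # plane of the two 1-2 edges, superimposing their directions.
    R1 = _rotation_between(u_edge, v_edge)

    # Step 3: spin about the now-common 1-2 edge to bring vertex 3 into
    # the target plane, on the correct side.
    e = v_edge / np.linalg.norm(v_edge)
    a = R1 @ (src[2] - src[0])
    b = tgt[2] - tgt[0]
    a_perp = a - np.dot(a, e) * e
    b_perp = b - np.dot(b, e) * e
    if np.linalg.norm(a_perp) < 1e-12 or np.linalg.norm(b_perp) < 1e-12:
        # Vertex 3 on the 1-2 line would have failed the area check already.
        R2 = np.eye(3)
    else:
        an = a_perp / np.linalg.norm(a_perp)
        bn = b_perp / np.linalg.norm(b_perp)
        angle = np.arctan2(float(np.dot(np.cross(an, bn), e)), float(np.dot(an, bn)))
        R2 = _axis_angle(e, angle)

    R = R2 @ R1
    t = tgt[0] - R @ src[0]
    return RigidPose(rotation=R, translation=t)


def fit_rigid_procrustes(
    source: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidPose:
    """Weighted orthogonal-Procrustes (Kabsch) rigid fit, det(R) = +1.

    Minimizes sum_i w_i ||R s_i + t - t_i||^2 over proper rigid transforms.
    The smallest singular direction is negated when the unconstrained
    optimum is a reflection.

    Raises
    ------
    ValueError
        For fewer than 3 points or collinear input.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise ValueError("need n >= 3 matched point pairs")
    if weights is None:
        w = np.ones(src.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (src.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mu_s = w @ src
    mu_t = w @ tgt
    sc = src - mu_s
    tc = tgt - mu_t
    # Collinearity check: second singular value of the centred cloud.
    if np.linalg.svd(sc, compute_uv=False)[1] < 1e-9:
        raise ValueError("source points are collinear")
    H = (sc * w[:, None]).T @ tc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidPose(rotation=R, translation=t)


@dataclass
class RegistrationResult:
    """Per-vertebra neutral-position registration outcome."""

    poses: dict[Vertebra, RigidPose]
    rms_residuals_mm: dict[Vertebra, float]
    method: str
    triangles: dict[Vertebra, tuple[str, str, str]]


def _best_triangle(labels: list[str], pts: np.ndarray) -> tuple[int, int, int]:
    """Maximal-area marker triple (best conditioning); ties by label order."""
    best = None
    best_area = -1.0
    for idx in combinations(range(len(labels)), 3):
        i, j, k = idx
        area = 0.5 * np.linalg.norm(np.cross(pts[j] - pts[i], pts[k] - pts[i]))
        if area > best_area + 1e-12:
            best_area = area
            best = idx
    assert best is not None
    return best


def register_model_to_neutral(
    model: SpineModel,
    neutral_markers: dict[tuple[Vertebra, str], np.ndarray],
    method: str = "triangle",
    warn_rms_mm: float = 1.0,
) -> RegistrationResult:
    """Align each vertebra's local markers onto an observed neutral frame.

    Parameters
    ----------
    model : SpineModel
        Template with local marker coordinates.
    neutral_markers : dict
        Observed positions keyed by (vertebra, marker label); missing
        (occluded) markers are simply absent.
    method : {"triangle", "procrustes"}
        "triangle" fits the maximal-area marker triple with the
        constructive procedure; "procrustes" least-squares-fits all
        available markers.
    warn_rms_mm : float
        RMS residual above which a warning is emitted (the accepted
        matching tolerance is a user choice; 1.0 mm by default).

    Raises
    ------
    ValueError
        If any vertebra has fewer than 3 visible markers (the error names
        the vertebra).
    """
    if method not in ("triangle", "procrustes"):
        raise ValueError(f"unknown registration method {method!r}")
    poses: dict[Vertebra, RigidPose] = {}
    residuals: dict[Vertebra, float] = {}
    triangles: dict[Vertebra, tuple[str, str, str]] = {}
    for vid, geo in model.vertebrae.items():
        labels = [lb for lb in geo.marker_labels if (vid, lb) in neutral_markers]
        if len(labels) < 3:
            raise ValueError(
                f"vertebra {vid.value}: only {len(labels)} visible markers "
                "in the neutral frame (need >= 3)"
            )
        local = np.array([geo.markers_local[lb] for lb in labels])
        obs = np.array([neutral_markers[(vid, lb)] for lb in labels])
        if method == "triangle":
            i, j, k = _best_triangle(labels, local)
            triangles[vid] = (labels[i], labels[j], labels[k])
            pose = fit_rigid_triangle(local[[i, j, k]], obs[[i, j, k]])
        else:
            triangles[vid] = tuple(labels[:3])  # type: ignore[assignment]
            pose = fit_rigid_procrustes(local, obs)
        res = pose.apply(local) - obs
        rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
        if rms > warn_rms_mm:
            warnings.warn(
                f"vertebra {vid.value}: registration RMS {rms:.3f} mm exceeds "
                f"{warn_rms_mm} mm",
                stacklevel=2,
            )
        poses[vid] = pose
        residuals[vid] = rms
    return RegistrationResult(
        poses=poses, rms_residuals_mm=residuals, method=method, triangles=triangles
    )
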