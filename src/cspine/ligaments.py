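"""Tension-only spring ligament mechanics.

Each ligament is a straight-line spring between its origin and insertion:
elongation beyond rest length produces force F = k·Δl (springs cannot
push; Δl ≤ 0 gives zero force), and pressure is engineering stress over a
constant effective cross-section, P = F / A_eff.  Every row of the
published per-condition state tables satisfies exactly these two formulas,
so the linear law is the implemented default; a user-supplied
force-displacement curve can replace it per ligament for nonlinear
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import Condition, Direction, LigamentSpec, Vertebra
from .pose import RigidPose
from .reference_tables import REFERENCE_STATE_TABLES, ReferenceRow

__all__ = [
    "LigamentStateRow",
    "ligament_length",
    "spring_force",
    "pressure",
    "build_state_table",
    "state_table_frame",
    "compare_with_reference",
]

#: Optional nonlinear hook: maps elongation (mm) to force (N).
ForceCurve = Callable[[float], float]

#: CSV column order mirroring the published tables.
STATE_COLUMNS = [
    "Ligaments",
    "Length change (mm)",
    "Rigidity (N/mm)",
    "Stress (N)",
    "Pressure (MPa)",
]


@dataclass
class LigamentStateRow:
    """Mechanical state of one ligament under one loading condition."""

    ligament: str
    length_change_dl: float
    rigidity_k: float
    stress_F: float
    pressure_P: float
    condition: Condition
    direction: Direction

    def __post_init__(self) -> None:
        if self.rigidity_k <= 0:
            raise ValueError("rigidity must be positive")
        expected_F = self.rigidity_k * max(self.length_change_dl, 0.0)
        if not np.isclose(self.stress_F, expected_F, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"{self.ligament}: stress {self.stress_F} inconsistent with "
                f"k*max(dl,0) = {expected_F}"
            )
        if self.stress_F < 0 or self.pressure_P < 0:
            raise ValueError("stress and pressure must be non-negative")


def ligament_length(
    pose_origin: RigidPose,
    pose_insertion: RigidPose,
    spec: LigamentSpec,
    model,
) -> float:
    """Current straight-line length between the two attachment points (mm).

    ``pose_origin`` / ``pose_insertion`` are the poses of the vertebrae
    carrying the origin and insertion, mapping neutral laboratory
    coordinates to the current frame; neutral attachment coordinates come
    from the model template.
    """
    p0 = pose_origin.apply(model.attachment_world(*spec.origin))
    p1 = pose_insertion.apply(model.attachment_world(*spec.insertion))
    return float(np.linalg.norm(p1 - p0))


def spring_force(
    dl: float, k: float, curve: ForceCurve | None = None
) -> float:
    """Tension-only spring force: F = k·Δl for Δl > 0, else 0 (N).

    A ``curve`` overrides the linear law (still clamped to tension only).

    Raises
    ------
    ValueError
        For non-positive stiffness.
    """
    if k <= 0:
        raise ValueError("rigidity must be positive")
    if dl <= 0:
        return 0.0
    if curve is not None:
        return max(float(curve(dl)), 0.0)
    return k * dl


def pressure(F: float, A_eff: float) -> float:
    """Engineering stress P = F / A_eff (MPa; N over mm²).

    Raises
    ------
    ValueError
        For zero or negative area.
    """
    if A_eff <= 0:
        raise ValueError("effective area must be positive")
    return F / A_eff


def build_state_table(
    dl_by_ligament: dict[str, float],
    specs: list[LigamentSpec],
    condition: Condition,
    direction: Direction,
    curves: dict[str, ForceCurve] | None = None,
) -> list[LigamentStateRow]:
    """Compute the per-ligament mechanical state from length changes.

    Raises
    ------
    KeyError
        For a length change naming a ligament with no specification.
    """
    spec_by_name = {s.name: s for s in specs}
    rows = []
    for name, dl in dl_by_ligament.items():
        if name not in spec_by_name:
            raise KeyError(f"unknown ligament name {name!r}")
        spec = spec_by_name[name]
        curve = (curves or {}).get(name)
        F = spring_force(dl, spec.rigidity_k, curve)
        P = pressure(F, spec.effective_area_A_eff)
        rows.append(
            LigamentStateRow(
                ligament=name,
                length_change_dl=dl,
                rigidity_k=spec.rigidity_k,
                stress_F=F,
                pressure_P=P,
                condition=Condition(condition),
                direction=Direction(direction),
            )
        )
    return rows


def state_table_frame(rows: list[LigamentStateRow]) -> pd.DataFrame:
    """State rows as a DataFrame in the published column order."""
    return pd.DataFrame(
        [
            {
                "Ligaments": r.ligament,
                "Length change (mm)": r.length_change_dl,
                "Rigidity (N/mm)": r.rigidity_k,
                "Stress (N)": r.stress_F,
                "Pressure (MPa)": r.pressure_P,
            }
            for r in rows
        ],
        columns=STATE_COLUMNS,
    )


def compare_with_reference(
    condition: Condition,
    direction: Direction,
    specs: list[LigamentSpec],
    flag_rtol: float = 5e-3,
) -> pd.DataFrame:
    """Recompute one published state table from its (Δl, k) columns.

    Returns a frame with computed vs published stress and pressure, their
    relative errors, and a ``flagged`` column marking published cells that
    are not reproducible from their own row beyond ``flag_rtol`` (0.5%
    default) — known for the alar and posterior-longitudinal rows of the
    instability-extension table.
    """
    ref = REFERENCE_STATE_TABLES[(Condition(condition), Direction(direction))]
    dl = {r.ligament: r.length_change_mm for r in ref}
    rows = build_state_table(dl, specs, condition, direction)
    by_name = {r.ligament: r for r in rows}
    out = []
    for r in ref:
        c = by_name[r.ligament]
        stress_rel = abs(c.stress_F - r.stress_N) / abs(r.stress_N)
        pressure_rel = abs(c.pressure_P - r.pressure_MPa) / abs(r.pressure_MPa)
        out.append(
            {
                "Ligaments": r.ligament,
                "Length change (mm)": r.length_change_mm,
                "Rigidity (N/mm)": r.rigidity_N_per_mm,
                "Stress computed (N)": c.stress_F,
                "Stress published (N)": r.stress_N,
                "Stress rel err": stress_rel,
                "Pressure computed (MPa)": c.pressure_P,
                "Pressure published (MPa)": r.pressure_MPa,
                "Pressure rel err": pressure_rel,
                "flagged": bool(
                    stress_rel > flag_rtol or pressure_rel > flag_rtol
                ),
            }
        )
    return pd.DataFrame(out)
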