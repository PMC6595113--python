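"""Published per-condition ligament state tables (study reference data).

Each table lists, for one (condition, direction) pair, the six monitored
ligament entities with their length change Δl (mm), rigidity k (N/mm), and
the published stress (N) and pressure (MPa) cells.  These are the inputs
and reference outputs the mechanics module reproduces; the
instability-extension table contains two rows that are internally
inconsistent as printed (the alar stress cell and the posterior-
longitudinal pressure cell) and are flagged, not matched, by the
comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Condition, Direction

__all__ = ["ReferenceRow", "REFERENCE_STATE_TABLES", "LIGAMENT_ENTITY_NAMES"]


@dataclass(frozen=True)
class ReferenceRow:
    ligament: str
    length_change_mm: float
    rigidity_N_per_mm: float
    stress_N: float
    pressure_MPa: float


#: Canonical names of the six monitored entities, in table order.
LIGAMENT_ENTITY_NAMES: list[str] = [
    "Alar ligament",
    "Ligamenta flavum (C1-C2)",
    "Anterior longitudinal ligament (C1-C2)",
    "Posterior longitudinal ligament (C2-C3)",
    "Apical odontoid ligament",
    "Cruciate ligament (longitudinal)",
]

REFERENCE_STATE_TABLES: dict[
    tuple[Condition, Direction], list[ReferenceRow]
] = {
    (Condition.PHYSIOLOGICAL, Direction.FLEXION): [
        ReferenceRow("Alar ligament", 0.0708, 25.32, 1.792656, 0.174044272),
        ReferenceRow("Ligamenta flavum (C1-C2)", 3.9, 11.6, 45.24, 0.902994012),
        ReferenceRow("Anterior longitudinal ligament (C1-C2)", 1.957, 24.0, 46.968, 7.699672131),
        ReferenceRow("Posterior longitudinal ligament (C2-C3)", 0.0559, 26.34, 1.472406, 0.272667778),
        ReferenceRow("Apical odontoid ligament", 0.915, 28.6, 26.169, 10.4676),
        ReferenceRow("Cruciate ligament (longitudinal)", 0.409, 38.0, 15.542, 2.285588235),
    ],
    (Condition.PHYSIOLOGICAL, Direction.EXTENSION): [
        ReferenceRow("Alar ligament", 1.159, 25.32, 29.34588, 2.849114563),
        ReferenceRow("Ligamenta flavum (C1-C2)", 1.89, 11.6, 21.924, 0.43760479),
        ReferenceRow("Anterior longitudinal ligament (C1-C2)", 2.666, 24.0, 63.984, 10.48918033),
        ReferenceRow("Posterior longitudinal ligament (C2-C3)", 0.0278, 26.34, 0.732252, 0.135602222),
        ReferenceRow("Apical odontoid ligament", 2.24345, 28.6, 64.16267, 25.665068),
        ReferenceRow("Cruciate ligament (longitudinal)", 0.4153, 38.0, 15.7814, 2.320794118),
    ],
    (Condition.INSTABILITY, Direction.FLEXION): [
        ReferenceRow("Alar ligament", 0.2018, 25.32, 5.109576, 0.49607534),
        ReferenceRow("Ligamenta flavum (C1-C2)", 5.227, 11.6, 60.6332, 1.210243513),
        ReferenceRow("Anterior longitudinal ligament (C1-C2)", 2.566, 24.0, 61.584, 10.0957377),
        ReferenceRow("Posterior longitudinal ligament (C2-C3)", 0.056, 26.34, 1.47504, 0.273155556),
        ReferenceRow("Apical odontoid ligament", 0.583, 28.6, 16.6738, 6.66952),
        ReferenceRow("Cruciate ligament (longitudinal)", 0.777, 38.0, 29.526, 4.342058824),
    ],
    (Condition.INSTABILITY, Direction.EXTENSION): [
        ReferenceRow("Alar ligament", 3.303, 25.32, 88.035, 8.12146443),
        ReferenceRow("Ligamenta flavum (C1-C2)", 2.53, 11.6, 29.35, 0.58546877),
        ReferenceRow("Anterior longitudinal ligament (C1-C2)", 3.496, 24.0, 83.89, 13.7522021),
        ReferenceRow("Posterior longitudinal ligament (C2-C3)", 0.028, 26.34, 0.7348, 0.13554872),
        ReferenceRow("Apical odontoid ligament", 1.429, 28.6, 40.87, 16.351397),
        ReferenceRow("Cruciate ligament (longitudinal)", 0.7889, 38.0, 29.97, 4.40887307),
    ],
}
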