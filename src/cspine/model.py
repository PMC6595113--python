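"""Domain model of the occipito-atlanto-axial complex (C0–C3).

The upper cervical spine is modelled as four rigid bodies — occiput (C0),
atlas (C1), axis (C2) and a fixed C3 base — connected by 22 tension-only
spring ligaments and three sagittal revolute joints.  This module defines
the domain types (vertebra geometry, ligament specifications, contact and
load constants, the clinical instability criterion) and embeds the default
parameter tables.

Coordinate convention
---------------------
Right-handed laboratory frame: +X anterior, +Y left (medio-lateral),
+Z cranial.  Each vertebra carries a body frame with origin at the
vertebral body centre, aligned with the laboratory frame in the neutral
position (foramen magnum horizontal, zero applied moment).  Flexion is a
positive rotation of the upper vertebra about the lower vertebra's +Y
axis.  Units: mm, N, MPa, degrees; moments in N·mm (1 N·m = 1000 N·mm at
the configuration boundary).

Effective areas
---------------
Two cross-sections are carried per ligament: the nominal published
cross-section (``cross_section_A``) and the effective area
(``effective_area_A_eff``) under which the published per-condition
stress/pressure tables are internally consistent (pressure = force /
effective area).  For the flavum, anterior- and posterior-longitudinal
ligaments the two agree; for the alar (10.3 vs 3.4 mm²) and apical
odontoid (2.5 vs 2.7 mm²) they differ, and the cruciate ligament has no
nominal value.  Pressure computations use the effective area throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from itertools import combinations

import numpy as np

__all__ = [
    "Vertebra",
    "Joint",
    "Direction",
    "Condition",
    "VertebraGeometry",
    "LigamentSpec",
    "ContactSpec",
    "LoadCase",
    "InstabilityCriterion",
    "SpineModel",
    "MATERIAL_PROPERTIES",
    "default_ligament_table",
    "effective_area_from_row",
    "load_template_geometry",
]


class Vertebra(str, Enum):
    """Rigid bodies of the complex; C0 is the occiput, C3 the fixed base."""

    C0 = "C0"
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"

    @property
    def level(self) -> int:
        return int(self.value[1])


class Joint(str, Enum):
    """Intervertebral joints, named upper-lower."""

    C0C1 = "C0C1"
    C1C2 = "C1C2"
    C2C3 = "C2C3"

    @property
    def upper(self) -> Vertebra:
        return Vertebra(self.value[:2])

    @property
    def lower(self) -> Vertebra:
        return Vertebra(self.value[2:])


class Direction(str, Enum):
    FLEXION = "flexion"
    EXTENSION = "extension"


class Condition(str, Enum):
    PHYSIOLOGICAL = "physiological"
    INSTABILITY = "instability"


def _as_point(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError(f"expected a finite 3-vector, got {x!r}")
    return p


def _triangle_area(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p2 - p1, p3 - p1)))


@dataclass
class VertebraGeometry:
    """Rigid vertebra: labelled marker and ligament-attachment coordinates.

    ``markers_local`` are the four screw-mounted optical marker positions in
    the body frame (mm); ``attachments_local`` are named ligament
    origin/insertion points.  ``origin_world`` places the body frame in the
    laboratory frame at neutral.
    """

    id: Vertebra
    markers_local: dict[str, np.ndarray]
    attachments_local: dict[str, np.ndarray]
    origin_world: np.ndarray
    sagittal_reference_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0])
    )

    def __post_init__(self) -> None:
        self.markers_local = {k: _as_point(v) for k, v in self.markers_local.items()}
        self.attachments_local = {
            k: _as_point(v) for k, v in self.attachments_local.items()
        }
        self.origin_world = _as_point(self.origin_world)
        self.sagittal_reference_axis = _as_point(self.sagittal_reference_axis)
        n = np.linalg.norm(self.sagittal_reference_axis)
        if not np.isclose(n, 1.0):
            raise ValueError(f"{self.id}: sagittal reference axis must be unit length")
        if len(self.markers_local) < 3:
            raise ValueError(f"{self.id}: needs at least 3 markers")
        if not self._has_noncollinear_triple():
            raise ValueError(f"{self.id}: markers are collinear (area <= 1 mm^2)")

    def _has_noncollinear_triple(self) -> bool:
        pts = list(self.markers_local.values())
        return any(
            _triangle_area(a, b, c) > 1.0 for a, b, c in combinations(pts, 3)
        )

    @property
    def marker_labels(self) -> list[str]:
        return list(self.markers_local)

    def marker_array(self) -> np.ndarray:
        """(n_markers, 3) local marker coordinates in label order."""
        return np.array([self.markers_local[k] for k in self.marker_labels])

    def attachment_world(self, name: str) -> np.ndarray:
        """Neutral-position laboratory coordinates of a named attachment."""
        return self.attachments_local[name] + self.origin_world


@dataclass
class LigamentSpec:
    """One spring-unit ligament: endpoints, stiffness and cross-sections.

    ``rigidity_k`` is the spring stiffness in N/mm; ``effective_area_A_eff``
    (mm²) is used for pressure = force / area.  ``cross_section_A``,
    ``elastic_modulus_E`` and ``poisson_nu`` mirror the published material
    table and are informational.
    """

    name: str
    category: str
    origin: tuple[Vertebra, str]
    insertion: tuple[Vertebra, str]
    rigidity_k: float
    effective_area_A_eff: float
    rest_length_L0: float
    cross_section_A: float | None = None
    elastic_modulus_E: float | None = None
    poisson_nu: float | None = None

    def __post_init__(self) -> None:
        if self.rigidity_k <= 0:
            raise ValueError(f"{self.name}: rigidity must be positive")
        if self.effective_area_A_eff <= 0:
            raise ValueError(f"{self.name}: effective area must be positive")
        if self.rest_length_L0 <= 0:
            raise ValueError(f"{self.name}: rest length must be positive")
        lo, hi = self.origin[0].level, self.insertion[0].level
        if abs(lo - hi) > 2:
            raise ValueError(
                f"{self.name}: endpoints must lie on the same or adjacent "
                f"vertebral complex (got {self.origin[0]}-{self.insertion[0]})"
            )

    def spans(self, joint: Joint) -> bool:
        """True when the ligament crosses the given joint."""
        a = min(self.origin[0].level, self.insertion[0].level)
        b = max(self.origin[0].level, self.insertion[0].level)
        return a <= joint.upper.level and joint.lower.level <= b


@dataclass
class ContactSpec:
    """Zygapophyseal (facet) contact constants: six sliding pairs C0–C3."""

    friction_mu: float = 0.10
    clearance_mm: float = 0.01
    n_pairs: int = 6

    def __post_init__(self) -> None:
        if self.friction_mu < 0:
            raise ValueError("friction coefficient must be non-negative")
        if self.clearance_mm < 0:
            raise ValueError("joint clearance must be non-negative")
        if self.n_pairs != 6:
            raise ValueError("the complex has exactly 6 facet contact pairs")


@dataclass
class LoadCase:
    """Compressive preload at the occiput plus a sagittal moment.

    Defaults emulate the in vitro protocol: 100 N along the cranio-caudal
    axis (head weight and extensor tone) and a 1.5 N·m moment about the
    medio-lateral axis, applied slowly (quasi-static).
    """

    preload_F: float = 100.0
    moment_M: float = 1500.0
    direction: Direction = Direction.FLEXION

    def __post_init__(self) -> None:
        if self.preload_F < 0:
            raise ValueError("preload must be non-negative")
        if self.moment_M < 0:
            raise ValueError("moment must be non-negative")
        self.direction = Direction(self.direction)

    @property
    def signed_moment(self) -> float:
        """Moment with the flexion-positive sign convention, N·mm."""
        return self.moment_M if self.direction is Direction.FLEXION else -self.moment_M


@dataclass
class InstabilityCriterion:
    """Radiographic cervical-instability thresholds.

    Instability is indicated by intervertebral angulation of more than 11°
    or horizontal displacement exceeding 3.5 mm (strict inequalities).
    """

    angle_threshold_deg: float = 11.0
    displacement_threshold_mm: float = 3.5

    def __post_init__(self) -> None:
        if self.angle_threshold_deg <= 0 or self.displacement_threshold_mm <= 0:
            raise ValueError("instability thresholds must be strictly positive")


#: Published bulk material block (elastic modulus MPa, Poisson ratio,
#: nominal cross-section mm²; None where not printed).  Bone, cartilage and
#: disc entries are metadata only — the rigid-body model does not use them.
MATERIAL_PROPERTIES: dict[str, dict[str, float | None]] = {
    "Cortical bone": {"E": 12000.0, "nu": 0.3, "A": None},
    "Cancellous bone": {"E": 100.0, "nu": 0.35, "A": None},
    "Cartilage": {"E": 500.0, "nu": 0.4, "A": None},
    "Intervertebral discs": {"E": 20.0, "nu": 0.45, "A": None},
    "Apical odontoid ligament": {"E": None, "nu": None, "A": 2.7},
    "Tectorial membrane": {"E": 20.0, "nu": 0.45, "A": 1.2},
    "Intertransverse ligament": {"E": 50.0, "nu": 0.45, "A": 13.1},
    "Interspinal ligaments": {"E": 28.0, "nu": 0.45, "A": 13.1},
    "Supraspinous ligament": {"E": 28.0, "nu": 0.45, "A": 13.1},
    "Flavum ligament": {"E": 50.0, "nu": 0.45, "A": 50.1},
    "Atlantoaxial collateral ligament": {"E": 30.0, "nu": 0.45, "A": 3.7},
    "Occipital collateral ligament": {"E": 30.0, "nu": 0.45, "A": 4.1},
    "Capsular ligament": {"E": 20.0, "nu": 0.45, "A": 46.6},
    "Anterior longitudinal ligament": {"E": 20.0, "nu": 0.45, "A": 6.1},
    "Posterior longitudinal ligament": {"E": 70.0, "nu": 0.45, "A": 5.4},
    "Alar ligament": {"E": 30.0, "nu": 0.45, "A": 3.4},
    "Anterior atlanto-occipital membrane": {"E": 20.0, "nu": 0.45, "A": 2.8},
    "Posterior atlanto-occipital membrane": {"E": 20.0, "nu": 0.45, "A": 3.3},
}

#: Stiffness (N/mm) and effective area (mm²) of the six tabulated ligament
#: entities, as used by the published per-condition state tables.
_TABULATED_MECHANICS: dict[str, tuple[float, float]] = {
    "alar": (25.32, 10.3),
    "flavum": (11.6, 50.1),
    "anterior_longitudinal": (24.0, 6.1),
    "posterior_longitudinal": (26.34, 5.4),
    "apical_odontoid": (28.6, 2.5),
    "cruciate": (38.0, 6.8),
}

#: category -> material-table row name (for E, nu, nominal A lookups).
_CATEGORY_MATERIAL: dict[str, str] = {
    "apical_odontoid": "Apical odontoid ligament",
    "intertransverse": "Intertransverse ligament",
    "interspinal": "Interspinal ligaments",
    "supraspinous": "Supraspinous ligament",
    "flavum": "Flavum ligament",
    "atlantoaxial_collateral": "Atlantoaxial collateral ligament",
    "occipital_collateral": "Occipital collateral ligament",
    "capsular": "Capsular ligament",
    "anterior_longitudinal": "Anterior longitudinal ligament",
    "posterior_longitudinal": "Posterior longitudinal ligament",
    "alar": "Alar ligament",
}

# (name, category, (origin vertebra, point), (insertion vertebra, point))
_LIGAMENT_LAYOUT: list[tuple[str, str, tuple[str, str], tuple[str, str]]] = [
    ("Apical odontoid ligament", "apical_odontoid", ("C2", "dens_tip"), ("C0", "basion")),
    ("Alar ligament", "alar", ("C2", "dens_alar"), ("C0", "condyle_alar")),
    ("Cruciate ligament (longitudinal)", "cruciate", ("C2", "cruciate_lower"), ("C0", "cruciate_upper")),
    ("Anterior longitudinal ligament (C1-C2)", "anterior_longitudinal", ("C2", "all_lower"), ("C1", "all_upper")),
    ("Posterior longitudinal ligament (C2-C3)", "posterior_longitudinal", ("C3", "pll_lower"), ("C2", "pll_upper")),
    ("Ligamenta flavum (C1-C2)", "flavum", ("C2", "flavum12_lower"), ("C1", "flavum12_upper")),
    ("Ligamenta flavum (C2-C3)", "flavum", ("C3", "flavum23_lower"), ("C2", "flavum23_upper")),
    ("Interspinal ligament (C1-C2)", "interspinal", ("C2", "interspinal12_lower"), ("C1", "interspinal12_upper")),
    ("Interspinal ligament (C2-C3)", "interspinal", ("C3", "interspinal23_lower"), ("C2", "interspinal23_upper")),
    ("Supraspinous ligament", "supraspinous", ("C3", "supraspinous_lower"), ("C2", "supraspinous_upper")),
    ("Intertransverse ligament (C1-C2 left)", "intertransverse", ("C2", "itl12_lower_left"), ("C1", "itl12_upper_left")),
    ("Intertransverse ligament (C1-C2 right)", "intertransverse", ("C2", "itl12_lower_right"), ("C1", "itl12_upper_right")),
    ("Intertransverse ligament (C2-C3 left)", "intertransverse", ("C3", "itl23_lower_left"), ("C2", "itl23_upper_left")),
    ("Intertransverse ligament (C2-C3 right)", "intertransverse", ("C3", "itl23_lower_right"), ("C2", "itl23_upper_right")),
    ("Atlantoaxial collateral ligament", "atlantoaxial_collateral", ("C2", "aa_collateral_lower"), ("C1", "aa_collateral_upper")),
    ("Occipital collateral ligament", "occipital_collateral", ("C1", "occ_collateral_lower"), ("C0", "occ_collateral_upper")),
    ("Capsular ligament (C0-C1 left)", "capsular", ("C1", "capsule01_lower_left"), ("C0", "capsule01_upper_left")),
    ("Capsular ligament (C0-C1 right)", "capsular", ("C1", "capsule01_lower_right"), ("C0", "capsule01_upper_right")),
    ("Capsular ligament (C1-C2 left)", "capsular", ("C2", "capsule12_lower_left"), ("C1", "capsule12_upper_left")),
    ("Capsular ligament (C1-C2 right)", "capsular", ("C2", "capsule12_lower_right"), ("C1", "capsule12_upper_right")),
    ("Capsular ligament (C2-C3 left)", "capsular", ("C3", "capsule23_lower_left"), ("C2", "capsule23_upper_left")),
    ("Capsular ligament (C2-C3 right)", "capsular", ("C3", "capsule23_lower_right"), ("C2", "capsule23_upper_right")),
]

#: Expected multiset of ligament categories (total 22).
CATEGORY_COUNTS: dict[str, int] = {
    "apical_odontoid": 1,
    "intertransverse": 4,
    "interspinal": 2,
    "supraspinous": 1,
    "flavum": 2,
    "atlantoaxial_collateral": 1,
    "occipital_collateral": 1,
    "capsular": 6,
    "anterior_longitudinal": 1,
    "posterior_longitudinal": 1,
    "alar": 1,
    "cruciate": 1,
}


def load_template_geometry() -> dict:
    """Load the versioned JSON template shipped with the package."""
    with resources.files("cspine.data").joinpath("template_geometry.json").open() as fh:
        return json.load(fh)


def effective_area_from_row(stress_F: float, pressure_P: float) -> float:
    """Effective cross-section (mm²) consistent with a (force, pressure) pair.

    Calibration helper: A_eff = F / P reconciles the nominal material table
    with the per-condition state tables.

    Raises
    ------
    ValueError
        If ``pressure_P`` is zero or negative.
    """
    if pressure_P <= 0:
        raise ValueError("pressure must be strictly positive")
    return stress_F / pressure_P


@dataclass
class SpineModel:
    """Rigid vertebrae plus the ligament specification table."""

    vertebrae: dict[Vertebra, VertebraGeometry]
    joint_centers_world: dict[Joint, np.ndarray]
    ligaments: list[LigamentSpec]

    def __post_init__(self) -> None:
        for j in Joint:
            if j not in self.joint_centers_world:
                raise ValueError(f"missing joint center for {j.value}")
        self.joint_centers_world = {
            j: _as_point(c) for j, c in self.joint_centers_world.items()
        }

    @classmethod
    def default(cls) -> "SpineModel":
        """Canonical template geometry with the default 22-ligament table."""
        tpl = load_template_geometry()
        vertebrae = {
            Vertebra(vid): VertebraGeometry(
                id=Vertebra(vid),
                markers_local=v["markers_local"],
                attachments_local=v["attachments_local"],
                origin_world=v["origin_world"],
                sagittal_reference_axis=v["sagittal_reference_axis"],
            )
            for vid, v in tpl["vertebrae"].items()
        }
        centers = {Joint(k): v for k, v in tpl["joint_centers_world"].items()}
        model = cls(vertebrae=vertebrae, joint_centers_world=centers, ligaments=[])
        model.ligaments = default_ligament_table(model)
        return model

    def attachment_world(self, vertebra: Vertebra, name: str) -> np.ndarray:
        return self.vertebrae[vertebra].attachment_world(name)

    def ligament(self, name: str) -> LigamentSpec:
        """Look up a ligament by exact name, else by category keyword.

        A bare anatomical name ("Flavum ligament", "Alar ligament") resolves
        to the representative instance of its category (layout order, i.e.
        the upper-most segment first).
        """
        for spec in self.ligaments:
            if spec.name == name:
                return spec
        key = (
            name.lower()
            .replace("ligamenta ", "")
            .replace(" ligament", "")
            .replace("ligament ", "")
            .strip()
            .replace(" ", "_")
        )
        for spec in self.ligaments:
            if spec.category == key or key in spec.category:
                return spec
        raise KeyError(f"unknown ligament {name!r}")


def default_ligament_table(model: SpineModel | None = None) -> list[LigamentSpec]:
    """The default 22-spring ligament table.

    Stiffness of the six tabulated entities (alar, flavum, anterior/
    posterior longitudinal, apical odontoid, cruciate) comes from the
    published per-condition tables; the remaining springs use k = E·A/L0
    from the material block and the template rest length.  Effective areas
    follow the published state tables where those differ from the nominal
    cross-sections (alar 10.3, apical odontoid 2.5, cruciate 6.8 mm²).
    """
    if model is None:
        model = SpineModel.default()
    specs: list[LigamentSpec] = []
    for name, category, (ov, op), (iv, ip) in _LIGAMENT_LAYOUT:
        origin = (Vertebra(ov), op)
        insertion = (Vertebra(iv), ip)
        p0 = model.attachment_world(*origin)
        p1 = model.attachment_world(*insertion)
        L0 = float(np.linalg.norm(p1 - p0))
        mat = MATERIAL_PROPERTIES.get(_CATEGORY_MATERIAL.get(category, ""), {})
        E = mat.get("E")
        nu = mat.get("nu")
        A = mat.get("A")
        if category in _TABULATED_MECHANICS:
            k, a_eff = _TABULATED_MECHANICS[category]
        else:
            if E is None or A is None:
                raise RuntimeError(f"no stiffness source for {name}")
            k = E * A / L0
            a_eff = A
        specs.append(
            LigamentSpec(
                name=name,
                category=category,
                origin=origin,
                insertion=insertion,
                rigidity_k=k,
                effective_area_A_eff=a_eff,
                rest_length_L0=L0,
                cross_section_A=A,
                elastic_modulus_E=E,
                poisson_nu=nu,
            )
        )
    counts: dict[str, int] = {}
    for s in specs:
        counts[s.category] = counts.get(s.category, 0) + 1
    assert counts == CATEGORY_COUNTS and len(specs) == 22
    return specs
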