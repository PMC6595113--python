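"""Model-validation statistics: regression, literature ranges, agreement.

Three checks mirror how dynamic spine models are validated in practice:

1. ordinary least-squares regression of experimental strain against
   model-predicted strain (slope, intercept, R²);
2. containment of the model's end-range angles within published cadaver
   ranges of motion for the atlanto-occipital and atlanto-axial joints;
3. a paired agreement test between model angles and angles recomputed
   from specimen marker trajectories (two-sided paired t-test, α = 0.05;
   Wilcoxon signed-rank available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import Direction, Joint
from .kinematics import RomSummary

__all__ = [
    "RegressionResult",
    "LiteratureRange",
    "LITERATURE_ROM_RANGES",
    "REFERENCE_MODEL_ANGLES",
    "REFERENCE_TRAJECTORY_ANGLES",
    "linear_regression",
    "range_check",
    "paired_agreement_test",
    "validation_report",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass
class LiteratureRange:
    """Published cadaver ROM interval (deg) for one movement and segment.

    ``decimals`` records the printed precision of the bounds; containment
    is judged at that precision (half-ULP tolerance), since a value can
    only be compared against an interval as finely as the interval is
    printed.
    """

    movement: Direction
    segment: Joint
    low_deg: float
    high_deg: float
    decimals: int = 1

    def __post_init__(self) -> None:
        if not self.low_deg < self.high_deg:
            raise ValueError("interval must have low < high")

    @property
    def tolerance(self) -> float:
        return 0.5 * 10.0 ** (-self.decimals)

    def contains(self, angle_deg: float) -> bool:
        tol = self.tolerance
        return (self.low_deg - tol) <= angle_deg <= (self.high_deg + tol)


#: Cadaver flexion/extension ROM intervals for the upper cervical joints
#: (0.3- and 1.5-N·m loading protocols from the classic in vitro series).
LITERATURE_ROM_RANGES: list[LiteratureRange] = [
    LiteratureRange(Direction.FLEXION, Joint.C0C1, 1.9, 11.4),
    LiteratureRange(Direction.FLEXION, Joint.C1C2, 1.0, 8.8),
    LiteratureRange(Direction.EXTENSION, Joint.C0C1, 10.8, 17.2),
    LiteratureRange(Direction.EXTENSION, Joint.C1C2, 6.0, 16.0),
]

#: Published model end-range angles (deg), ordered (C0C1 flex, C1C2 flex,
#: C0C1 ext, C1C2 ext) x (physiological, instability) — and the matching
#: angles recomputed from the in vitro specimen marker trajectories.
REFERENCE_MODEL_ANGLES: list[float] = [3.49, 8.84, 11.16, 14.20, 5.51, 13.70, 12.96, 17.20]
REFERENCE_TRAJECTORY_ANGLES: list[float] = [3.82, 8.01, 10.4, 14.89, 4.91, 14.08, 12.55, 16.41]


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y = slope·x + intercept with R² = 1 − SSres/SStot.

    Raises
    ------
    ValueError
        For length mismatch, n < 3, or constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n=int(x.size),
    )


def range_check(
    rom: RomSummary | dict[tuple[Joint, Direction], float],
    ranges: list[LiteratureRange] | None = None,
) -> dict[tuple[Joint, Direction], bool]:
    """Check each reported end-range angle against its literature interval.

    Containment is inclusive at the bounds and judged at the printed
    precision of the interval (see :class:`LiteratureRange`).

    Raises
    ------
    KeyError
        If a reported (joint, movement) has no interval.
    """
    if ranges is None:
        ranges = LITERATURE_ROM_RANGES
    by_key = {(r.segment, r.movement): r for r in ranges}
    if isinstance(rom, RomSummary):
        angles: dict[tuple[Joint, Direction], float] = {}
        for j, v in rom.flexion_deg.items():
            if (j, Direction.FLEXION) in by_key:
                angles[(j, Direction.FLEXION)] = v
        for j, v in rom.extension_deg.items():
            if (j, Direction.EXTENSION) in by_key:
                angles[(j, Direction.EXTENSION)] = v
        missing = set(by_key) - set(angles)
        if missing:
            raise KeyError(f"ROM summary missing entries for {sorted(missing)}")
    else:
        angles = dict(rom)
        for key in angles:
            if key not in by_key:
                raise KeyError(f"no literature interval for {key}")
    return {key: by_key[key].contains(v) for key, v in angles.items()}


def paired_agreement_test(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    method: str = "ttest",
) -> tuple[float, float, bool]:
    """Two-sided paired test of angle agreement; agree when p > alpha.

    Pairs are matched by joint × direction × condition.  ``method`` is
    "ttest" (paired t, default) or "wilcoxon" (signed-rank).  Degenerate
    inputs: identical pairs give p = 1 by convention; zero-variance
    differences with nonzero mean give p = 0.

    Returns
    -------
    (statistic, p_value, agree)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D sets with n >= 2")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0, True
    if np.ptp(d) == 0:  # constant nonzero difference
        return float(np.sign(d[0]) * np.inf), 0.0, False
    if method == "ttest":
        t, p = stats.ttest_rel(a, b)
    elif method == "wilcoxon":
        t, p = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(t), float(p), bool(p > alpha)


def validation_report(
    rom: RomSummary | dict[tuple[Joint, Direction], float],
    model_angles: np.ndarray | None = None,
    trajectory_angles: np.ndarray | None = None,
    regression_xy: tuple[np.ndarray, np.ndarray] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Assemble the three validation blocks into one JSON-ready report."""
    if model_angles is None:
        model_angles = np.array(REFERENCE_MODEL_ANGLES)
    if trajectory_angles is None:
        trajectory_angles = np.array(REFERENCE_TRAJECTORY_ANGLES)
    containment = range_check(rom)
    stat, p, agree = paired_agreement_test(
        np.asarray(model_angles), np.asarray(trajectory_angles), alpha=alpha
    )
    report: dict = {
        "containment": {
            f"{j.value}:{d.value}": ok for (j, d), ok in containment.items()
        },
        "all_within_literature": bool(all(containment.values())),
        "agreement": {
            "statistic": stat,
            "p_value": p,
            "agree": agree,
            "alpha": alpha,
            "n_pairs": int(np.asarray(model_angles).size),
        },
    }
    if regression_xy is not None:
        reg = linear_regression(*regression_xy)
        report["regression"] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "n": reg.n,
        }
    return report
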