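"""Reference-organ statistics and approach-specific SUV thresholding.

Six shipped approaches define, per bone group (axial skeleton vs
extremities), either a reference-organ-derived threshold
(organ median/max x multiplier) or an absolute SUV.  A voxel is segmented
as infiltration-positive when its SUV is greater than *or equal to* the
resolved threshold of its group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from bmquant.image_model import BoneGroup, PatientStudy

__all__ = [
    "ReferenceStats",
    "ThresholdRule",
    "ThresholdApproach",
    "InfiltrationMask",
    "DEFAULT_APPROACHES",
    "compute_reference_stats",
    "resolve_thresholds",
    "apply_threshold",
    "load_approaches",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Whole-organ reference statistics used to resolve relative thresholds."""

    liver_median: float
    liver_max: float
    gluteus_median: float
    liver_voxels: int
    gluteus_voxels: int

    def __post_init__(self) -> None:
        if self.liver_max < self.liver_median:
            raise ValueError("liver_max < liver_median")
        for name in ("liver_median", "liver_max", "gluteus_median"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ThresholdRule:
    """One per-group rule: either organ statistic x multiplier, or an absolute SUV.

    ``organ`` in {"liver", "gluteus"}, ``statistic`` in {"median", "max"}.
    Exactly one of (organ, statistic, multiplier) or ``absolute`` is given.
    """

    organ: str | None = None
    statistic: str | None = None
    multiplier: float | None = None
    absolute: float | None = None

    def __post_init__(self) -> None:
        if self.absolute is not None:
            if self.organ is not None or self.statistic is not None or self.multiplier is not None:
                raise ValueError("rule is either absolute or organ-relative, not both")
            if self.absolute < 0:
                raise ValueError("absolute threshold must be >= 0")
        else:
            if self.organ not in ("liver", "gluteus"):
                raise ValueError(f"unknown reference organ {self.organ!r}")
            if self.statistic not in ("median", "max"):
                raise ValueError(f"unknown statistic {self.statistic!r}")
            if self.multiplier is None or self.multiplier <= 0:
                raise ValueError("multiplier must be > 0")

    def resolve(self, stats: ReferenceStats | None) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        if stats is None:
            raise ValueError("rule references a reference-organ statistic but no stats given")
        key = f"{self.organ}_{self.statistic}"
        try:
            base = getattr(stats, key)
        except AttributeError as exc:
            raise ValueError(f"reference statistic {key!r} unavailable") from exc
        return float(base) * float(self.multiplier)

    def describe(self) -> str:
        if self.absolute is not None:
            return f"SUV >= {self.absolute:g}"
        return f"{self.organ} SUV_{self.statistic} x {self.multiplier:g}"


@dataclass(frozen=True)
class ThresholdApproach:
    """A named pair of (axial, extremity) threshold rules."""

    id: str
    axial_rule: ThresholdRule
    extremity_rule: ThresholdRule


def _liver_median(mult: float) -> ThresholdRule:
    return ThresholdRule(organ="liver", statistic="median", multiplier=mult)


_GLUTEUS_X4 = ThresholdRule(organ="gluteus", statistic="median", multiplier=4.0)
_LIVER_MAX = ThresholdRule(organ="liver", statistic="max", multiplier=1.0)

#: The six shipped threshold approaches.
DEFAULT_APPROACHES: dict[str, ThresholdApproach] = {
    "1": ThresholdApproach("1", _liver_median(1.1), _GLUTEUS_X4),
    "2": ThresholdApproach("2", _liver_median(1.5), _GLUTEUS_X4),
    "3": ThresholdApproach("3", _liver_median(2.0), _GLUTEUS_X4),
    "4": ThresholdApproach("4", ThresholdRule(absolute=2.5), ThresholdRule(absolute=2.5)),
    "5": ThresholdApproach("5", ThresholdRule(absolute=2.5), ThresholdRule(absolute=2.0)),
    "6": ThresholdApproach("6", _LIVER_MAX, _LIVER_MAX),
}


@dataclass
class InfiltrationMask:
    """Binary infiltration mask plus provenance of the thresholds that produced it."""

    mask: np.ndarray
    approach_id: str
    axial_threshold: float
    extremity_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("infiltration mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def compute_reference_stats(study: PatientStudy) -> ReferenceStats:
    """Whole-organ liver/gluteus statistics (median = midpoint of central order stats).

    Medians are used for the relative approaches because they are robust to
    outlier voxels from small segmentation or alignment inconsistencies.
    """
    liver = study.seg.group_mask(BoneGroup.REFERENCE_LIVER)
    gluteus = study.seg.group_mask(BoneGroup.REFERENCE_GLUTEUS)
    if not liver.any():
        raise ValueError("liver reference mask is empty")
    if not gluteus.any():
        raise ValueError("gluteus maximus reference mask is empty")
    liver_suv = study.suv.values[liver]
    gluteus_suv = study.suv.values[gluteus]
    return ReferenceStats(
        liver_median=float(np.median(liver_suv)),
        liver_max=float(liver_suv.max()),
        gluteus_median=float(np.median(gluteus_suv)),
        liver_voxels=int(liver.sum()),
        gluteus_voxels=int(gluteus.sum()),
    )


def resolve_thresholds(
    approach: ThresholdApproach, stats: ReferenceStats | None
) -> dict[str, float]:
    """Resolve an approach against reference stats -> numeric per-group thresholds."""
    return {
        "axial": approach.axial_rule.resolve(stats),
        "extremity": approach.extremity_rule.resolve(stats),
    }


def apply_threshold(
    study: PatientStudy,
    thresholds: dict[str, float],
    approach_id: str = "custom",
) -> InfiltrationMask:
    """Segment voxels with SUV >= their group threshold inside the skeletal mask.

    Only AXIAL and EXTREMITY voxels are eligible; reference organs,
    EXCLUDED labels (skull) and background are never set.
    """
    t_ax = float(thresholds["axial"])
    t_ex = float(thresholds["extremity"])
    suv = study.suv.values
    axial = study.seg.group_mask(BoneGroup.AXIAL)
    extremity = study.seg.group_mask(BoneGroup.EXTREMITY)
    mask = (axial & (suv >= t_ax)) | (extremity & (suv >= t_ex))
    return InfiltrationMask(mask, approach_id, t_ax, t_ex)


def load_approaches(path: str | Path) -> dict[str, ThresholdApproach]:
    """Load custom approach definitions from YAML/JSON.

    Schema: a list of ``{id, axial: RULE, extremity: RULE}`` where RULE is
    either ``{absolute: <suv>}`` or
    ``{organ: liver|gluteus, statistic: median|max, multiplier: <x>}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "approaches" in raw:
        raw = raw["approaches"]

    def _rule(d: dict) -> ThresholdRule:
        if "absolute" in d:
            return ThresholdRule(absolute=float(d["absolute"]))
        return ThresholdRule(
            organ=str(d["organ"]),
            statistic=str(d.get("statistic", "median")),
            multiplier=float(d.get("multiplier", 1.0)),
        )

    out: dict[str, ThresholdApproach] = {}
    for entry in raw:
        aid = str(entry["id"])
        out[aid] = ThresholdApproach(aid, _rule(entry["axial"]), _rule(entry["extremity"]))
    return out
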