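"""Whole-body and per-group MTV / TLG from the refined infiltration mask.

MTV (mL) = number of segmented voxels x physical voxel volume.
TLG (g)  = SUVmean over the segmented voxels x MTV (SUV taken as g/mL, so
SUV x mL carries grams).  An empty mask legitimately yields MTV = TLG = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bmquant.image_model import BoneGroup, PatientStudy
from bmquant.refinement import LesionComponent
from bmquant.thresholding import InfiltrationMask

__all__ = ["PatientMetrics", "compute_metrics"]


@dataclass
class PatientMetrics:
    """Per-patient, per-approach burden summary."""

    patient_id: str
    approach_id: str
    mtv_ml: float
    tlg_g: float
    suv_mean_lesional: float
    n_components: int
    axial_mtv_ml: float
    extremity_mtv_ml: float
    axial_tlg_g: float
    extremity_tlg_g: float
    axial_threshold: float = float("nan")
    extremity_threshold: float = float("nan")
    components: list[LesionComponent] = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "approach": self.approach_id,
            "mtv_ml": self.mtv_ml,
            "tlg_g": self.tlg_g,
            "suv_mean_lesional": self.suv_mean_lesional,
            "n_components": self.n_components,
            "axial_mtv_ml": self.axial_mtv_ml,
            "extremity_mtv_ml": self.extremity_mtv_ml,
            "axial_tlg_g": self.axial_tlg_g,
            "extremity_tlg_g": self.extremity_tlg_g,
            "axial_threshold": self.axial_threshold,
            "extremity_threshold": self.extremity_threshold,
        }


def compute_metrics(
    study: PatientStudy,
    refined: InfiltrationMask,
    components: list[LesionComponent] | None = None,
) -> PatientMetrics:
    """Compute MTV, TLG and per-group sub-totals over a refined mask.

    Voxels spanning both bone groups are attributed to their own label's
    group, which keeps whole-body totals exactly additive:
    ``mtv_ml == axial_mtv_ml + extremity_mtv_ml`` (same for TLG).
    """
    if refined.mask.shape != study.suv.shape:
        raise ValueError(
            f"refined mask shape {refined.mask.shape} != SUV shape {study.suv.shape}"
        )
    vv = study.suv.voxel_volume_ml
    suv = study.suv.values
    mask = refined.mask

    def _totals(m: np.ndarray) -> tuple[float, float, float]:
        n = int(m.sum())
        if n == 0:
            return 0.0, 0.0, 0.0
        mtv = n * vv
        mean = float(suv[m].mean())
        return mtv, mean * mtv, mean

    mtv, tlg, suv_mean = _totals(mask)
    ax_mtv, ax_tlg, _ = _totals(mask & study.seg.group_mask(BoneGroup.AXIAL))
    ex_mtv, ex_tlg, _ = _totals(mask & study.seg.group_mask(BoneGroup.EXTREMITY))

    return PatientMetrics(
        patient_id=study.patient_id,
        approach_id=refined.approach_id,
        mtv_ml=mtv,
        tlg_g=tlg,
        suv_mean_lesional=suv_mean,
        n_components=len(components) if components is not None else -1,
        axial_mtv_ml=ax_mtv,
        extremity_mtv_ml=ex_mtv,
        axial_tlg_g=ax_tlg,
        extremity_tlg_g=ex_tlg,
        axial_threshold=refined.axial_threshold,
        extremity_threshold=refined.extremity_threshold,
        components=list(components) if components is not None else [],
    )
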