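import numpy as np
import pytest

from bmquant.image_model import BoneGroup, PatientStudy, SegmentationMap, SuvVolume

# label ids used by the toy-study builder (matching the phantom convention)
VERTEBRAE, FEMORA, LIVER, GLUTEUS, SKULL = 1, 12, 18, 19, 20

TOY_LABEL_DICT = {
    VERTEBRAE: "vertebrae",
    FEMORA: "femora",
    LIVER: "liver",
    GLUTEUS: "gluteus_maximus",
    SKULL: "skull",
}
TOY_GROUPS = {
    VERTEBRAE: BoneGroup.AXIAL,
    FEMORA: BoneGroup.EXTREMITY,
    LIVER: BoneGroup.REFERENCE_LIVER,
    GLUTEUS: BoneGroup.REFERENCE_GLUTEUS,
    SKULL: BoneGroup.EXCLUDED,
}


def build_study(
    suv_values: np.ndarray,
    labels: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    patient_id: str = "toy",
) -> PatientStudy:
    """Assemble a PatientStudy from raw arrays using the toy label convention."""
    suv = SuvVolume(np.asarray(suv_values, dtype=float), spacing)
    seg = SegmentationMap(
        np.asarray(labels, dtype=np.int16), TOY_LABEL_DICT, TOY_GROUPS, spacing, suv.affine
    )
    return PatientStudy(suv, seg, patient_id)


@pytest.fixture
def toy_study() -> PatientStudy:
    """A 6x6x8 study: axial block, extremity block, liver, gluteus."""
    labels = np.zeros((6, 6, 8), dtype=np.int16)
    labels[1:3, 1:5, 1:7] = VERTEBRAE
    labels[4:5, 1:5, 1:7] = FEMORA
    labels[1:3, 1:3, 7:8] = LIVER
    labels[4:6, 4:6, 7:8] = GLUTEUS
    suv = np.full((6, 6, 8), 0.2)
    suv[labels == VERTEBRAE] = 1.0
    suv[labels == FEMORA] = 0.7
    suv[labels == LIVER] = 2.0
    suv[labels == GLUTEUS] = 0.5
    return build_study(suv, labels)
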