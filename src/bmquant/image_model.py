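"""Core volumetric data types and NIfTI/JSON readers-writers.

Geometry convention: volumes are stored as 3D numpy arrays in 0-based voxel
index order ``(i, j, k)``; physical placement is carried by a NIfTI-style
4x4 affine.  Label maps are transferred between grids by nearest-neighbor
lookup through the affines — labels are categorical, interpolation would
invent anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoneGroup",
    "SuvVolume",
    "SegmentationMap",
    "PatientStudy",
    "AXIAL_BONES",
    "EXTREMITY_BONES",
    "read_study",
    "read_label_dict",
    "resample_labels",
    "suv_from_activity",
    "write_suv_nifti",
    "write_labels_nifti",
]


class BoneGroup(str, Enum):
    """Role of a label in the quantification: thresholded bone, reference organ, or neither."""

    AXIAL = "AXIAL"
    EXTREMITY = "EXTREMITY"
    REFERENCE_LIVER = "REFERENCE_LIVER"
    REFERENCE_GLUTEUS = "REFERENCE_GLUTEUS"
    EXCLUDED = "EXCLUDED"
    BACKGROUND = "BACKGROUND"


#: Axial-skeleton bone names recognised by the default grouping.
AXIAL_BONES = frozenset(
    {"vertebrae", "scapulae", "clavicles", "sternum", "ribs", "sacrum", "pelvic_bones"}
)

#: Extremity bone names recognised by the default grouping.
EXTREMITY_BONES = frozenset(
    {
        "humeri",
        "ulnae",
        "radii",
        "hands",
        "femora",
        "patellae",
        "tibiae",
        "fibulae",
        "tali",
        "feet",
    }
)


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class SuvVolume:
    """A 3D standardized-uptake-value grid with voxel geometry.

    Parameters
    ----------
    values
        3D array of SUV (dimensionless body-weight SUV, conventionally g/mL).
        Must be finite and non-negative.
    spacing
        Per-axis voxel edge length in mm; all components strictly positive.
    affine
        4x4 voxel-to-world matrix (NIfTI convention).  Defaults to a
        diagonal affine built from ``spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"SUV volume must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV volume contains negative values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Physical voxel volume in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class SegmentationMap:
    """Integer label grid co-registered with a :class:`SuvVolume`.

    ``label_dict`` maps label id -> anatomical name, ``group_scheme`` maps
    label id -> :class:`BoneGroup`.  Label 0 is background by convention.
    """

    labels: np.ndarray
    label_dict: dict[int, str]
    group_scheme: dict[int, BoneGroup]
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("label map has non-integer values")
            self.labels = rounded.astype(np.int32)
        self.label_dict = {int(k): str(v) for k, v in self.label_dict.items()}
        self.group_scheme = {int(k): BoneGroup(v) for k, v in self.group_scheme.items()}
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.label_dict)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} present in grid but absent from label_dict")
        for lid in self.label_dict:
            self.group_scheme.setdefault(lid, BoneGroup.BACKGROUND)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def group_mask(self, group: BoneGroup) -> np.ndarray:
        """Boolean mask of all voxels whose label belongs to ``group``."""
        ids = [lid for lid, g in self.group_scheme.items() if g is group]
        if not ids:
            return np.zeros(self.shape, dtype=bool)
        return np.isin(self.labels, ids)

    def organ_mask(self, name: str) -> np.ndarray:
        ids = [lid for lid, nm in self.label_dict.items() if nm == name]
        if not ids:
            raise KeyError(f"no label named {name!r} in label dictionary")
        return np.isin(self.labels, ids)

    def has_organ(self, name: str) -> bool:
        return any(nm == name for nm in self.label_dict.values())


@dataclass
class PatientStudy:
    """A geometrically aligned (SUV volume, segmentation) pair for one patient."""

    suv: SuvVolume
    seg: SegmentationMap
    patient_id: str = "anonymous"

    def __post_init__(self) -> None:
        if self.suv.shape != self.seg.shape:
            raise ValueError(
                f"SUV shape {self.suv.shape} != segmentation shape {self.seg.shape}; "
                "resample labels first"
            )
        if not np.allclose(self.suv.spacing, self.seg.spacing, rtol=1e-5):
            raise ValueError(
                f"SUV spacing {self.suv.spacing} != segmentation spacing {self.seg.spacing}"
            )


def suv_from_activity(
    activity_conc_bq_ml: float, injected_dose_bq: float, body_weight_g: float
) -> float:
    """Body-weight SUV from an activity concentration.

    SUV = activity concentration (Bq/mL) x body weight (g) / injected dose (Bq).
    """
    if activity_conc_bq_ml <= 0 or injected_dose_bq <= 0 or body_weight_g <= 0:
        raise ValueError("activity concentration, dose and weight must all be > 0")
    return float(activity_conc_bq_ml) * float(body_weight_g) / float(injected_dose_bq)


def read_label_dict(path: str | Path) -> tuple[dict[int, str], dict[int, BoneGroup]]:
    """Read a JSON label dictionary.

    Accepted forms: a list of ``{"id": int, "name": str, "group": str}``
    records, or a mapping ``{"<id>": {"name": ..., "group": ...}}``.  When
    ``group`` is omitted it is inferred from the name (axial/extremity bone
    tables, ``liver``, ``gluteus_maximus``, ``skull`` -> EXCLUDED).
    """
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        records = [{"id": int(k), **v} for k, v in raw.items()]
    else:
        records = list(raw)
    label_dict: dict[int, str] = {}
    group_scheme: dict[int, BoneGroup] = {}
    for rec in records:
        lid = int(rec["id"])
        name = str(rec["name"])
        label_dict[lid] = name
        if "group" in rec and rec["group"]:
            group_scheme[lid] = BoneGroup(rec["group"])
        else:
            group_scheme[lid] = infer_group(name)
    return label_dict, group_scheme


def infer_group(name: str) -> BoneGroup:
    """Default anatomical-name -> group mapping (skull is always EXCLUDED)."""
    if name in AXIAL_BONES:
        return BoneGroup.AXIAL
    if name in EXTREMITY_BONES:
        return BoneGroup.EXTREMITY
    if name == "liver":
        return BoneGroup.REFERENCE_LIVER
    if name in ("gluteus_maximus", "gluteus"):
        return BoneGroup.REFERENCE_GLUTEUS
    if name == "skull":
        return BoneGroup.EXCLUDED
    return BoneGroup.BACKGROUND


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=np.float64)


def read_study(
    pet_path: str | Path,
    seg_path: str | Path,
    label_dict_path: str | Path,
    patient_id: str | None = None,
) -> PatientStudy:
    """Load a PET SUV volume plus segmentation and return an aligned study.

    The segmentation is resampled (nearest-neighbor through the header
    affines) onto the PET grid whenever the two geometries differ.  Raises
    if the liver or gluteus maximus reference organ is missing — both are
    required by the reference-organ threshold approaches.
    """
    for p in (pet_path, seg_path, label_dict_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    pet_data, pet_spacing, pet_affine = _load_nifti(pet_path)
    seg_data, seg_spacing, seg_affine = _load_nifti(seg_path)
    label_dict, group_scheme = read_label_dict(label_dict_path)

    suv = SuvVolume(pet_data, pet_spacing, pet_affine)
    seg = SegmentationMap(seg_data, label_dict, group_scheme, seg_spacing, seg_affine)

    for organ in ("liver", "gluteus_maximus"):
        if not seg.has_organ(organ):
            raise ValueError(
                f"segmentation label dictionary is missing the reference organ {organ!r} "
                "(required to resolve reference-organ thresholds)"
            )

    if seg.shape != suv.shape or not np.allclose(seg.affine, suv.affine, atol=1e-6):
        seg = resample_labels(seg, target_shape=suv.shape, target_affine=suv.affine,
                              target_spacing=suv.spacing)
    if patient_id is None:
        patient_id = Path(pet_path).name.split(".")[0]
    return PatientStudy(suv=suv, seg=seg, patient_id=patient_id)


def resample_labels(
    seg: SegmentationMap,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    target_spacing: tuple[float, float, float],
) -> SegmentationMap:
    """Nearest-neighbor transfer of a label map onto a target grid.

    Every target voxel centre is mapped through ``target_affine`` to world
    space and back through the inverse source affine; the nearest source
    voxel supplies the label, out-of-field voxels become background.  The
    output label set is therefore a subset of the input label set.
    """
    target_affine = np.asarray(target_affine, dtype=np.float64)
    if seg.shape == tuple(target_shape) and np.allclose(seg.affine, target_affine, atol=1e-9):
        return SegmentationMap(
            seg.labels.copy(), dict(seg.label_dict), dict(seg.group_scheme),
            target_spacing, target_affine.copy(),
        )
    try:
        src_inv = np.linalg.inv(seg.affine)
    except np.linalg.LinAlgError as exc:
        raise ValueError("segmentation affine is singular; cannot resample") from exc

    ii, jj, kk = np.meshgrid(
        np.arange(target_shape[0]), np.arange(target_shape[1]), np.arange(target_shape[2]),
        indexing="ij",
    )
    tgt_idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src_idx = src_inv @ (target_affine @ tgt_idx)
    src_ijk = np.rint(src_idx[:3]).astype(np.int64)
    inb = (
        (src_ijk[0] >= 0) & (src_ijk[0] < seg.shape[0])
        & (src_ijk[1] >= 0) & (src_ijk[1] < seg.shape[1])
        & (src_ijk[2] >= 0) & (src_ijk[2] < seg.shape[2])
    )
    out = np.zeros(tgt_idx.shape[1], dtype=seg.labels.dtype)
    out[inb] = seg.labels[src_ijk[0, inb], src_ijk[1, inb], src_ijk[2, inb]]
    return SegmentationMap(
        out.reshape(target_shape), dict(seg.label_dict), dict(seg.group_scheme),
        target_spacing, target_affine.copy(),
    )


def write_suv_nifti(suv: SuvVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(suv.values.astype(np.float64), suv.affine), str(path))


def write_labels_nifti(seg: SegmentationMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(seg.labels.astype(np.int16), seg.affine), str(path))


def write_label_dict(seg: SegmentationMap, path: str | Path) -> None:
    records = [
        {"id": lid, "name": seg.label_dict[lid], "group": seg.group_scheme[lid].value}
        for lid in sorted(seg.label_dict)
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
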