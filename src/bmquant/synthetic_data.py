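"""Synthetic digital phantoms and synthetic patient cohorts.

The phantom generator paints a simplified whole-body anatomy (17 bones,
liver, gluteus maximus, optional skull) into a label grid, assigns per-organ
base SUV plus diffuse marrow uptake, inserts uniform ellipsoidal focal
lesions clipped to the skeleton, optionally blurs with an isotropic Gaussian
point-spread function (spill-over emulation) and adds truncated-at-zero
Gaussian noise.  Ground truth records each lesion's voxelized volume so the
image pipeline can be validated exactly in the noise-free, PSF-free case.

The cohort generator draws (latent burden, marrow infiltration %,
beta2-microglobulin) from a Gaussian copula with a target Spearman
rank-correlation matrix, links burden monotonically to per-approach MTV/TLG,
and assigns visual groups from burden tertiles with optional label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from bmquant.image_model import (
    AXIAL_BONES,
    EXTREMITY_BONES,
    BoneGroup,
    SegmentationMap,
    SuvVolume,
    infer_group,
)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "PHANTOM_LABELS",
]

# label id -> anatomical name for the default phantom anatomy
PHANTOM_LABELS: dict[int, str] = {
    1: "vertebrae",
    2: "scapulae",
    3: "clavicles",
    4: "sternum",
    5: "ribs",
    6: "sacrum",
    7: "pelvic_bones",
    8: "humeri",
    9: "ulnae",
    10: "radii",
    11: "hands",
    12: "femora",
    13: "patellae",
    14: "tibiae",
    15: "fibulae",
    16: "tali",
    17: "feet",
    18: "liver",
    19: "gluteus_maximus",
    20: "skull",
}


@dataclass(frozen=True)
class LesionSpec:
    """One focal lesion: ellipsoid centre (fractional grid coords), radii in mm, uniform SUV."""

    center: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv: float

    def __post_init__(self) -> None:
        if any(not (0.0 <= c <= 1.0) for c in self.center):
            raise ValueError("lesion centre must be in fractional coordinates [0, 1]")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be > 0")
        if self.suv < 0:
            raise ValueError("lesion SUV must be >= 0")


@dataclass
class PhantomSpec:
    """Parameters of a digital whole-body phantom."""

    shape: tuple[int, int, int] = (96, 96, 192)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    diffuse_axial_suv: float = 1.2
    diffuse_extremity_suv: float = 0.8
    liver_suv: float = 2.2
    gluteus_suv: float = 0.5
    background_suv: float = 0.2
    skull_suv: float = 5.0
    include_skull: bool = False
    lesions: list[LesionSpec] = field(default_factory=list)
    psf_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 8 for s in self.shape):
            raise ValueError("phantom grid must be at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for suv in (
            self.diffuse_axial_suv,
            self.diffuse_extremity_suv,
            self.liver_suv,
            self.gluteus_suv,
            self.background_suv,
        ):
            if suv < 0:
                raise ValueError("SUV levels must be >= 0")


@dataclass
class GroundTruth:
    """Known truth for a generated phantom."""

    lesion_voxel_counts: list[int]
    lesion_volumes_ml: list[float]
    total_lesion_volume_ml: float
    diffuse_axial_suv: float
    diffuse_extremity_suv: float
    liver_suv: float
    gluteus_suv: float
    lesion_suvs: list[float]

    def to_dict(self) -> dict:
        return {
            "lesion_voxel_counts": self.lesion_voxel_counts,
            "lesion_volumes_ml": self.lesion_volumes_ml,
            "total_lesion_volume_ml": self.total_lesion_volume_ml,
            "diffuse_axial_suv": self.diffuse_axial_suv,
            "diffuse_extremity_suv": self.diffuse_extremity_suv,
            "liver_suv": self.liver_suv,
            "gluteus_suv": self.gluteus_suv,
            "lesion_suvs": self.lesion_suvs,
        }


# ---------------------------------------------------------------------------
# geometry painters (all coordinates fractional in [0, 1] per axis)

def _grid(shape):
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    return ii, jj, kk


def _box(labels, lid, x0, x1, y0, y1, z0, z1):
    nx, ny, nz = labels.shape
    sl = (
        slice(int(round(x0 * nx)), max(int(round(x0 * nx)) + 1, int(round(x1 * nx)))),
        slice(int(round(y0 * ny)), max(int(round(y0 * ny)) + 1, int(round(y1 * ny)))),
        slice(int(round(z0 * nz)), max(int(round(z0 * nz)) + 1, int(round(z1 * nz)))),
    )
    labels[sl] = lid


def _cylinder_z(labels, lid, cx, cy, r, z0, z1, ii, jj, kk):
    nx, ny, nz = labels.shape
    inside = (
        ((ii / nx - cx) ** 2 + (jj / ny - cy) ** 2 <= r**2)
        & (kk >= int(round(z0 * nz)))
        & (kk < max(int(round(z0 * nz)) + 1, int(round(z1 * nz))))
    )
    labels[inside] = lid


def _ellipsoid_mask(shape, center_frac, radii_vox):
    ii, jj, kk = _grid(shape)
    cx = center_frac[0] * (shape[0] - 1)
    cy = center_frac[1] * (shape[1] - 1)
    cz = center_frac[2] * (shape[2] - 1)
    return (
        ((ii - cx) / radii_vox[0]) ** 2
        + ((jj - cy) / radii_vox[1]) ** 2
        + ((kk - cz) / radii_vox[2]) ** 2
    ) <= 1.0


def _paint_anatomy(shape, include_skull: bool) -> np.ndarray:
    """Paint the default simplified anatomy; z axis runs feet (0) -> head (1)."""
    labels = np.zeros(shape, dtype=np.int16)
    ii, jj, kk = _grid(shape)

    # extremities (legs)
    for dx in (-0.13, 0.13):
        _cylinder_z(labels, 12, 0.5 + dx, 0.5, 0.045, 0.26, 0.44, ii, jj, kk)  # femora
        _box(labels, 13, 0.5 + dx - 0.03, 0.5 + dx + 0.03, 0.42, 0.48, 0.245, 0.26)  # patellae
        _cylinder_z(labels, 14, 0.5 + dx, 0.5, 0.04, 0.09, 0.245, ii, jj, kk)  # tibiae
        _cylinder_z(labels, 15, 0.5 + dx + 0.07, 0.5, 0.018, 0.09, 0.24, ii, jj, kk)  # fibulae
        _box(labels, 16, 0.5 + dx - 0.03, 0.5 + dx + 0.03, 0.47, 0.53, 0.065, 0.09)  # tali
        _box(labels, 17, 0.5 + dx - 0.04, 0.5 + dx + 0.04, 0.42, 0.6, 0.02, 0.065)  # feet
    # arms
    for dx in (-0.34, 0.34):
        _cylinder_z(labels, 8, 0.5 + dx, 0.5, 0.035, 0.68, 0.85, ii, jj, kk)  # humeri
        _cylinder_z(labels, 9, 0.5 + dx - 0.02, 0.5, 0.018, 0.52, 0.675, ii, jj, kk)  # ulnae
        _cylinder_z(labels, 10, 0.5 + dx + 0.025, 0.5, 0.018, 0.52, 0.675, ii, jj, kk)  # radii
        _box(labels, 11, 0.5 + dx - 0.04, 0.5 + dx + 0.04, 0.46, 0.54, 0.46, 0.52)  # hands
    # axial skeleton
    _box(labels, 5, 0.3, 0.7, 0.35, 0.42, 0.70, 0.86)  # ribs (anterior shell)
    _box(labels, 5, 0.3, 0.7, 0.62, 0.69, 0.70, 0.86)  # ribs (posterior shell)
    _box(labels, 4, 0.47, 0.53, 0.30, 0.35, 0.72, 0.82)  # sternum
    _box(labels, 2, 0.18, 0.28, 0.55, 0.68, 0.80, 0.875)  # scapula L
    _box(labels, 2, 0.72, 0.82, 0.55, 0.68, 0.80, 0.875)  # scapula R
    _box(labels, 3, 0.3, 0.46, 0.42, 0.47, 0.875, 0.895)  # clavicle L
    _box(labels, 3, 0.54, 0.7, 0.42, 0.47, 0.875, 0.895)  # clavicle R
    _cylinder_z(labels, 1, 0.5, 0.54, 0.05, 0.555, 0.90, ii, jj, kk)  # vertebrae
    _box(labels, 6, 0.45, 0.55, 0.48, 0.60, 0.52, 0.555)  # sacrum
    _box(labels, 7, 0.3, 0.44, 0.42, 0.62, 0.45, 0.55)  # pelvic bone L
    _box(labels, 7, 0.56, 0.7, 0.42, 0.62, 0.45, 0.55)  # pelvic bone R
    # reference organs
    liver = _ellipsoid_mask(
        shape,
        (0.31, 0.45, 0.665),
        (0.14 * shape[0], 0.13 * shape[1], 0.05 * shape[2]),
    )
    labels[liver & (labels == 0)] = 18
    _box(labels, 19, 0.33, 0.45, 0.68, 0.82, 0.44, 0.54)  # gluteus maximus L
    _box(labels, 19, 0.55, 0.67, 0.68, 0.82, 0.44, 0.54)  # gluteus maximus R
    if include_skull:
        skull = _ellipsoid_mask(
            shape, (0.5, 0.5, 0.955), (0.1 * shape[0], 0.1 * shape[1], 0.035 * shape[2])
        )
        labels[skull & (labels == 0)] = 20
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[SuvVolume, SegmentationMap, GroundTruth]:
    """Generate a phantom SUV volume, its label map, and ground truth.

    Lesions are painted uniformly at their stated SUV, clipped to skeletal
    labels; the recorded ground-truth volume of each lesion is its painted
    voxel count times the voxel volume.  With ``psf_sigma_mm == 0`` and
    ``noise_sd == 0`` the pipeline recovers these volumes exactly for any
    threshold strictly between the diffuse level and the lesion SUV.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    labels = _paint_anatomy(shape, spec.include_skull)

    label_dict = {
        lid: name
        for lid, name in PHANTOM_LABELS.items()
        if lid in np.unique(labels)
    }
    group_scheme = {lid: infer_group(name) for lid, name in label_dict.items()}

    suv = np.full(shape, spec.background_suv, dtype=np.float64)
    axial_ids = [lid for lid, n in label_dict.items() if n in AXIAL_BONES]
    extremity_ids = [lid for lid, n in label_dict.items() if n in EXTREMITY_BONES]
    suv[np.isin(labels, axial_ids)] = spec.diffuse_axial_suv
    suv[np.isin(labels, extremity_ids)] = spec.diffuse_extremity_suv
    suv[labels == 18] = spec.liver_suv
    suv[labels == 19] = spec.gluteus_suv
    if spec.include_skull:
        suv[labels == 20] = spec.skull_suv

    bone_mask = np.isin(labels, axial_ids + extremity_ids)
    voxel_ml = float(np.prod(spec.spacing)) / 1000.0
    lesion_counts: list[int] = []
    for li, lesion in enumerate(spec.lesions):
        radii_vox = tuple(r / s for r, s in zip(lesion.radii_mm, spec.spacing))
        ell = _ellipsoid_mask(shape, lesion.center, radii_vox)
        centre_idx = tuple(
            int(round(c * (n - 1))) for c, n in zip(lesion.center, shape)
        )
        if not bone_mask[centre_idx]:
            raise ValueError(
                f"lesion {li} centre {centre_idx} does not lie inside a bone label"
            )
        painted = ell & bone_mask
        suv[painted] = np.maximum(suv[painted], lesion.suv)
        lesion_counts.append(int(painted.sum()))

    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / s for s in spec.spacing]
        suv = ndimage.gaussian_filter(suv, sigma=sigma_vox, mode="constant", cval=0.0)
    if spec.noise_sd > 0:
        suv = suv + rng.normal(0.0, spec.noise_sd, size=shape)
    suv = np.clip(suv, 0.0, None)

    volume = SuvVolume(suv, spec.spacing)
    seg = SegmentationMap(labels, label_dict, group_scheme, spec.spacing, volume.affine)
    gt = GroundTruth(
        lesion_voxel_counts=lesion_counts,
        lesion_volumes_ml=[c * voxel_ml for c in lesion_counts],
        total_lesion_volume_ml=sum(lesion_counts) * voxel_ml,
        diffuse_axial_suv=spec.diffuse_axial_suv,
        diffuse_extremity_suv=spec.diffuse_extremity_suv,
        liver_suv=spec.liver_suv,
        gluteus_suv=spec.gluteus_suv,
        lesion_suvs=[l.suv for l in spec.lesions],
    )
    return volume, seg, gt


# ---------------------------------------------------------------------------
# cohort generator

#: relative MTV scale per shipped approach (stricter thresholds -> lower burden)
_APPROACH_SCALES = {"1": 1.0, "2": 0.35, "3": 0.12, "4": 0.5, "5": 0.55, "6": 0.04}


@dataclass
class CohortSpec:
    """Parameters of a synthetic patient cohort.

    ``rank_corr`` is the target Spearman correlation matrix among the latent
    variables (burden, infiltration, beta2-microglobulin), in that order.
    """

    n: int = 35
    rank_corr: np.ndarray = None  # type: ignore[assignment]
    group_noise: float = 0.0
    mtv_noise_sd: float = 0.0
    approaches: tuple[str, ...] = ("1", "2", "3", "4", "5", "6")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        if self.rank_corr is None:
            self.rank_corr = np.array(
                [[1.0, 0.4, 0.4], [0.4, 1.0, 0.35], [0.4, 0.35, 1.0]]
            )
        self.rank_corr = np.asarray(self.rank_corr, dtype=np.float64)
        if self.rank_corr.shape != (3, 3):
            raise ValueError("rank_corr must be 3x3")
        if not np.allclose(self.rank_corr, self.rank_corr.T):
            raise ValueError("rank_corr must be symmetric")
        if not (0.0 <= self.group_noise <= 1.0):
            raise ValueError("group_noise must be in [0, 1]")


def _copula_pearson(rank_corr: np.ndarray) -> np.ndarray:
    """Spearman targets -> Gaussian-copula Pearson matrix (2 sin(pi rho / 6))."""
    pearson = 2.0 * np.sin(np.pi * rank_corr / 6.0)
    np.fill_diagonal(pearson, 1.0)
    eig = np.linalg.eigvalsh(pearson)
    if eig.min() < -1e-10:
        raise ValueError("rank correlation matrix is not positive semidefinite")
    return pearson


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic per-patient cohort table.

    Columns: ``patient_id``, ``bm_infiltration_pct``, ``beta2_microglobulin``,
    ``visual_group`` (A/B/C), ``cytogenetic_risk`` (high/standard),
    ``iss_stage``, ``riss_stage``, and per approach ``mtv_approach_<id>`` /
    ``tlg_approach_<id>``.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pearson = _copula_pearson(spec.rank_corr)
    # eigen decomposition keeps near-singular (comonotone) targets usable
    w, v = np.linalg.eigh(pearson)
    w = np.clip(w, 0.0, None)
    chol_like = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((spec.n, 3)) @ chol_like.T
    u = stats.norm.cdf(z)

    burden = stats.lognorm.ppf(np.clip(u[:, 0], 1e-12, 1 - 1e-12), s=1.4, scale=130.0)
    infiltration = 100.0 * stats.beta.ppf(np.clip(u[:, 1], 1e-12, 1 - 1e-12), 1.5, 2.2)
    b2m = stats.lognorm.ppf(np.clip(u[:, 2], 1e-12, 1 - 1e-12), s=0.55, scale=2.7)

    rows: dict[str, np.ndarray | list] = {
        "patient_id": [f"P{idx:03d}" for idx in range(1, spec.n + 1)],
        "bm_infiltration_pct": infiltration,
        "beta2_microglobulin": b2m,
    }

    suv_mean = 2.5 + 1.5 * stats.norm.cdf(np.log(burden / 130.0) / 1.4)
    for aid in spec.approaches:
        scale = _APPROACH_SCALES.get(aid, 1.0)
        mtv = burden * scale
        if spec.mtv_noise_sd > 0:
            mtv = mtv * np.exp(rng.normal(0.0, spec.mtv_noise_sd, size=spec.n))
        rows[f"mtv_approach_{aid}"] = mtv
        rows[f"tlg_approach_{aid}"] = mtv * suv_mean

    # visual group from burden tertiles, with optional label noise
    tertiles = np.quantile(burden, [1 / 3, 2 / 3])
    group_idx = np.searchsorted(tertiles, burden, side="right")
    if spec.group_noise > 0:
        flip = rng.random(spec.n) < spec.group_noise
        group_idx = np.where(flip, rng.integers(0, 3, size=spec.n), group_idx)
    rows["visual_group"] = np.array(["A", "B", "C"])[group_idx]

    # cytogenetic risk: mildly burden-dependent
    u_risk = rng.random(spec.n)
    high = u_risk < (0.10 + 0.25 * stats.norm.cdf(np.log(burden / 130.0) / 1.4))
    rows["cytogenetic_risk"] = np.where(high, "high", "standard")

    iss = np.where(b2m < 3.5, 1, np.where(b2m <= 5.5, 2, 3))
    rows["iss_stage"] = iss
    riss = np.where((iss == 1) & ~high, 1, np.where((iss == 3) & high, 3, 2))
    rows["riss_stage"] = riss

    return pd.DataFrame(rows)
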