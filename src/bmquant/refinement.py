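"""Spill-over refinement of the raw infiltration mask.

Three steps: (1) every mask voxel is assigned to its local SUV maximum by a
priority-flood (Meyer-style) watershed restricted to the mask, (2) voxels
inherit the label of the maximum that flooded them, and (3) 18-connected
components smaller than a minimum physical volume (default 1 mL) are
removed.  18-connectivity means adjacency through faces and edges but not
corners (at most two nonzero index offsets).

Determinism: voxels of equal SUV are ordered lexicographically by index
``(i, j, k)``; a flat plateau of touching equal-height maxima becomes a
single region seeded at its lexicographically smallest voxel; a popped
voxel joins the labeled 18-neighbor of highest SUV (ties again broken
lexicographically).  With all-distinct SUVs this reproduces steepest-ascent
hill climbing exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from bmquant.image_model import BoneGroup, SegmentationMap
from bmquant.thresholding import InfiltrationMask

__all__ = [
    "NEIGHBORS_18",
    "RegionLabeling",
    "LesionComponent",
    "flood_assign",
    "filter_components",
    "structuring_element",
]

#: Offsets of the 18-neighborhood: faces + edges, no corners.
NEIGHBORS_18: tuple[tuple[int, int, int], ...] = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0) and abs(di) + abs(dj) + abs(dk) <= 2
)


def structuring_element(connectivity: int = 18) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


@dataclass
class RegionLabeling:
    """Watershed partition of a mask: region id per voxel, seed per region.

    ``region_labels`` is 0 outside the mask; region ids are 1..n_regions in
    order of their seeds' lexicographic position.  ``seeds[r]`` is the
    coordinate of the local maximum that seeded region ``r``; its SUV is the
    maximum SUV within the region.
    """

    region_labels: np.ndarray
    seeds: dict[int, tuple[int, int, int]]
    suv: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.seeds)

    @property
    def mask(self) -> np.ndarray:
        return self.region_labels > 0


@dataclass
class LesionComponent:
    """One surviving refined region."""

    component_id: int
    voxel_count: int
    volume_ml: float
    suv_mean: float
    suv_max: float
    seed: tuple[int, int, int]
    groups: tuple[str, ...] = field(default_factory=tuple)


def flood_assign(suv_values: np.ndarray, mask: np.ndarray | InfiltrationMask) -> RegionLabeling:
    """Partition the mask by assigning every voxel to its local SUV maximum.

    Local maxima (mask voxels with no strictly greater 18-neighbor inside
    the mask) seed the regions; touching equal-height maxima merge into one
    plateau region.  Remaining voxels are claimed in descending-SUV priority
    order by their highest-SUV already-labeled neighbor.  An empty mask
    yields an empty labeling.
    """
    suv_values = np.asarray(suv_values, dtype=np.float64)
    if isinstance(mask, InfiltrationMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != suv_values.shape:
        raise ValueError(f"mask shape {mask.shape} != SUV shape {suv_values.shape}")

    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return RegionLabeling(labels, {}, suv_values)

    # Local maxima: no strictly greater 18-neighbor within the mask.
    # grey_dilation with the 18-footprint gives the neighborhood max; outside-mask
    # voxels must not compete, so they are sunk to -inf first.
    neg_inf = np.float64(-np.inf)
    field_vals = np.where(mask, suv_values, neg_inf)
    footprint = structuring_element(18)
    footprint_nb = footprint.copy()
    footprint_nb[1, 1, 1] = False  # exclude the centre: strictness test
    nb_max = ndimage.grey_dilation(field_vals, footprint=footprint_nb, mode="constant",
                                   cval=neg_inf)
    is_max = mask & (field_vals >= nb_max)

    # Touching maxima necessarily share one SUV (else the lower one had a greater
    # neighbor), so plateau merging is plain 18-connected labeling of the maxima.
    plateau, n_plateau = ndimage.label(is_max, structure=footprint)

    # Deterministic region ids ordered by lexicographically smallest plateau voxel.
    seeds: dict[int, tuple[int, int, int]] = {}
    max_coords = np.argwhere(is_max)  # argwhere is lexicographic (i, j, k)
    first_voxel: dict[int, tuple[int, int, int]] = {}
    for coord in max_coords:
        pid = int(plateau[tuple(coord)])
        if pid not in first_voxel:
            first_voxel[pid] = tuple(int(c) for c in coord)
    ranked = sorted(first_voxel, key=lambda p: first_voxel[p])
    remap = np.zeros(n_plateau + 1, dtype=np.int32)
    for new_id, pid in enumerate(ranked, start=1):
        remap[pid] = new_id
        seeds[new_id] = first_voxel[pid]
    labels[is_max] = remap[plateau[is_max]]

    # Meyer-style priority flood of the remaining mask voxels.
    shape = mask.shape
    in_queue = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []

    def push_neighbors(i: int, j: int, k: int) -> None:
        for di, dj, dk in NEIGHBORS_18:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                if mask[ni, nj, nk] and labels[ni, nj, nk] == 0 and not in_queue[ni, nj, nk]:
                    in_queue[ni, nj, nk] = True
                    heapq.heappush(heap, (-suv_values[ni, nj, nk], ni, nj, nk))

    for (i, j, k) in map(tuple, np.argwhere(is_max)):
        push_neighbors(i, j, k)

    while heap:
        _, i, j, k = heapq.heappop(heap)
        if labels[i, j, k] != 0:
            continue
        best_label = 0
        best_suv = neg_inf
        best_coord: tuple[int, int, int] | None = None
        for di, dj, dk in NEIGHBORS_18:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                lab = labels[ni, nj, nk]
                if lab != 0:
                    s = suv_values[ni, nj, nk]
                    coord = (ni, nj, nk)
                    if s > best_suv or (s == best_suv and (best_coord is None or coord < best_coord)):
                        best_suv = s
                        best_label = lab
                        best_coord = coord
        labels[i, j, k] = best_label
        push_neighbors(i, j, k)

    return RegionLabeling(labels, seeds, suv_values)


def filter_components(
    labeling: RegionLabeling,
    spacing: tuple[float, float, float],
    min_volume_ml: float = 1.0,
    connectivity: int = 18,
    source: InfiltrationMask | None = None,
    seg: SegmentationMap | None = None,
    per_label_components: bool = True,
) -> tuple[InfiltrationMask, list[LesionComponent]]:
    """Remove small connected components and summarise the survivors.

    Components are maximal sets of voxels sharing one watershed region label
    and mutually 18-connected (``per_label_components=False`` instead labels
    components on the union mask, ignoring watershed boundaries).  Components
    with physical volume strictly below ``min_volume_ml`` are removed; a
    component of exactly the minimum volume survives.  Survivors are returned
    sorted by descending volume (ties by seed coordinate).
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    structure = structuring_element(connectivity)
    suv = labeling.suv

    refined = np.zeros(labeling.region_labels.shape, dtype=bool)
    raw_components: list[tuple[int, float, float, np.ndarray]] = []

    if per_label_components:
        region_ids = sorted(labeling.seeds)
        for rid in region_ids:
            region_mask = labeling.region_labels == rid
            comp_lab, n_comp = ndimage.label(region_mask, structure=structure)
            for c in range(1, n_comp + 1):
                comp_mask = comp_lab == c
                _collect(comp_mask, suv, voxel_ml, min_volume_ml, refined, raw_components)
    else:
        comp_lab, n_comp = ndimage.label(labeling.mask, structure=structure)
        for c in range(1, n_comp + 1):
            comp_mask = comp_lab == c
            _collect(comp_mask, suv, voxel_ml, min_volume_ml, refined, raw_components)

    # Sort survivors by descending volume, then by seed coordinate.
    raw_components.sort(key=lambda t: (-t[0], t[3]))
    components: list[LesionComponent] = []
    for cid, (count, mean, mx, seed_arr) in enumerate(raw_components, start=1):
        seed = tuple(int(x) for x in seed_arr)
        components.append(
            LesionComponent(
                component_id=cid,
                voxel_count=int(count),
                volume_ml=float(count) * voxel_ml,
                suv_mean=float(mean),
                suv_max=float(mx),
                seed=seed,  # type: ignore[arg-type]
            )
        )
    if seg is not None:
        _attach_groups(components, labeling, refined, seg)

    approach_id = source.approach_id if source is not None else "refined"
    t_ax = source.axial_threshold if source is not None else float("nan")
    t_ex = source.extremity_threshold if source is not None else float("nan")
    return InfiltrationMask(refined, approach_id, t_ax, t_ex), components


def _collect(comp_mask, suv, voxel_ml, min_volume_ml, refined, out) -> None:
    count = int(comp_mask.sum())
    vol = count * voxel_ml
    if vol < min_volume_ml:
        return
    vals = suv[comp_mask]
    coords = np.argwhere(comp_mask)
    top = vals.max()
    # seed = highest-SUV voxel in the component, lexicographic tie-break
    cand = coords[vals == top]
    seed = cand[np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))][0]
    refined[comp_mask] = True
    out.append((count, float(vals.mean()), float(top), tuple(int(x) for x in seed)))


def _attach_groups(components, labeling, refined, seg: SegmentationMap) -> None:
    """Record which bone groups each surviving component touches."""
    group_of_label = {lid: g for lid, g in seg.group_scheme.items()}
    structure = structuring_element(18)
    comp_lab, n = ndimage.label(refined, structure=structure)
    # map each LesionComponent to its connected blob via the seed voxel
    for comp in components:
        blob = comp_lab[comp.seed]
        if blob == 0:
            continue
        labs = np.unique(seg.labels[comp_lab == blob])
        groups = sorted(
            {
                group_of_label.get(int(l), BoneGroup.BACKGROUND).value
                for l in labs
                if int(l) != 0
            }
        )
        comp.groups = tuple(groups)
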