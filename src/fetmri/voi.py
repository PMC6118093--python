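"""Volume-of-interest definition.

The MRI VOI is the manually contoured enhancing lesion (supplied as a mask
file, or the ground-truth mask for synthetic cases). The PET VOI comes from
3-D auto-contouring: the connected component of voxels whose tumor-to-brain
ratio (TBR = uptake / normal-brain background) reaches the threshold (default
1.6). Lesions whose PET uptake never reaches the threshold are "PET-negative"
and analysed on the MRI mask transferred to the PET lattice instead. VOIs with
fewer than 100 voxels are excluded from texture analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .grids import LesionMask, VoxelGrid

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass(frozen=True)
class TbrParams:
    """PET auto-contouring parameters."""

    background: float
    threshold_ratio: float = 1.6
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background must be positive")
        if self.threshold_ratio <= 1:
            raise ValueError("threshold_ratio must exceed 1")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")


def autocontour_pet(
    pet: VoxelGrid,
    params: TbrParams,
    seed_voxel: tuple[int, int, int] | None = None,
) -> LesionMask:
    """Threshold at TBR >= ratio and keep one connected component.

    The component containing ``seed_voxel`` is returned when a seed is given;
    otherwise the largest. An empty mask (tagged ``pet_autocontour``) signals a
    PET-negative lesion.
    """
    if pet.modality != "PET":
        raise ValueError("autocontour_pet expects a PET grid")
    if seed_voxel is not None:
        seed_voxel = tuple(int(c) for c in seed_voxel)
        if any(c < 0 or c >= n for c, n in zip(seed_voxel, pet.shape)):
            raise IndexError(f"seed voxel {seed_voxel} outside grid {pet.shape}")
    above = pet.values >= params.threshold_ratio * params.background
    labels, n_comp = ndimage.label(above, structure=_STRUCTURES[params.connectivity])
    empty = LesionMask(np.zeros(pet.shape, dtype=bool), pet.spacing_mm, source="pet_autocontour")
    if n_comp == 0:
        logger.info("auto-contour: no voxel reaches TBR >= %.2f (PET-negative)", params.threshold_ratio)
        return empty
    if seed_voxel is not None:
        lab = labels[seed_voxel]
        if lab == 0:
            logger.info("auto-contour: seed voxel below threshold (PET-negative)")
            return empty
    else:
        sizes = np.bincount(labels.ravel())[1:]
        lab = 1 + int(np.argmax(sizes))
    return LesionMask(labels == lab, pet.spacing_mm, source="pet_autocontour")


def select_largest_lesion(masks: list[LesionMask]) -> LesionMask:
    """The mask with the most voxels; ties go to the first (logged)."""
    if not masks:
        raise ValueError("no masks to select from")
    counts = [m.n_voxels for m in masks]
    best = int(np.argmax(counts))
    if counts.count(counts[best]) > 1:
        logger.warning("largest-lesion tie at %d voxels; keeping the first", counts[best])
    return masks[best]


def enforce_min_voxels(mask: LesionMask, min_voxels: int = 100) -> bool:
    """True iff the VOI is large enough for texture analysis (>= min_voxels)."""
    accepted = mask.n_voxels >= min_voxels
    if not accepted:
        cause = "empty/PET-negative" if mask.n_voxels == 0 else f"{mask.n_voxels} voxels"
        logger.info("VOI rejected (<%d voxels): %s", min_voxels, cause)
    return accepted


def transfer_mask(mask: LesionMask, target: VoxelGrid) -> LesionMask:
    """Resample a mask onto a co-registered target lattice (nearest neighbour).

    Both lattices are taken to share the physical frame (origin at voxel
    (0,0,0) of each). Used when a PET-negative lesion borrows the MRI VOI.
    """
    src_spacing = np.asarray(mask.spacing_mm)
    tgt_spacing = np.asarray(target.spacing_mm)
    src_extent = (np.asarray(mask.shape) - 1) * src_spacing
    tgt_extent = (np.asarray(target.shape) - 1) * tgt_spacing
    if np.any(tgt_extent <= 0) or np.any(src_extent <= 0):
        raise ValueError("degenerate grid extent")
    if np.all(np.minimum(src_extent, tgt_extent) == 0):
        raise ValueError("grids have disjoint physical extents")
    grids = np.meshgrid(
        *[np.arange(n) * t / s for n, t, s in zip(target.shape, tgt_spacing, src_spacing)],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(
        mask.support.astype(float), coords, order=0, mode="constant", cval=0.0
    )
    return LesionMask(
        out.reshape(target.shape) > 0.5, target.spacing_mm, source="transferred_mri"
    )
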