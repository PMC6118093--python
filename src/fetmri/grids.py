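"""Voxel lattices and lesion masks.

A :class:`VoxelGrid` is a 3-D intensity lattice with per-axis spacing in mm,
tagged with its modality (PET or contrast-enhanced T1 MRI) and filter channel.
A :class:`LesionMask` is a boolean lattice on the same geometry defining the
volume of interest (VOI). The third array axis is the slice (axial) index.

Volumes and masks are serialised as NIfTI with the spacing carried in the
affine; masks are stored as 0/1 integers and read back as booleans.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("PET", "T1CE")
CHANNELS = ("unfiltered", "LoG", "DWT3")
MASK_SOURCES = ("manual_mri", "pet_autocontour", "transferred_mri")


@dataclasses.dataclass(frozen=True)
class VoxelGrid:
    """3-D intensity lattice with physical geometry and provenance tags."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "T1CE"
    channel: str = "unfiltered"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {values.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.channel != "unfiltered" and self.modality != "T1CE":
            # Filtered channels exist for MRI only; PET is analysed unfiltered.
            raise ValueError("LoG/DWT3 channels are defined for T1CE only")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "VoxelGrid":
        return dataclasses.replace(
            self, values=values, channel=self.channel if channel is None else channel
        )


@dataclasses.dataclass(frozen=True)
class LesionMask:
    """Boolean VOI support aligned to a companion grid."""

    support: np.ndarray
    spacing_mm: tuple[float, float, float]
    source: str = "manual_mri"

    def __post_init__(self) -> None:
        support = np.asarray(self.support).astype(bool)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if support.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got shape {support.shape}")
        if self.source not in MASK_SOURCES:
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.support.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def _affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    affine = np.diag(list(spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    return affine


def write_grid(grid: VoxelGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid.spacing_mm, grid.origin_mm))
    nib.save(img, str(path))
    return path


def read_grid(path: str | Path, modality: str = "T1CE", channel: str = "unfiltered") -> VoxelGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return VoxelGrid(
        values=np.asanyarray(img.dataobj, dtype=float),
        spacing_mm=spacing,
        origin_mm=origin,
        modality=modality,
        channel=channel,
    )


def write_mask(mask: LesionMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.support.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, source: str = "manual_mri") -> LesionMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(
        support=np.asanyarray(img.dataobj) > 0, spacing_mm=spacing, source=source
    )
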