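"""Reslicing and the two high-pass MRI filter channels.

The analysis uses T1CE MRI in three channels: unfiltered, after a 2-D
Laplacian-of-Gaussian filter (sigma 0.5 mm, 5x5 kernel, applied per axial
slice), and after reconstruction of the all-directions high-pass subband of a
first-level 3-D coiflet-1 wavelet decomposition (DWT3). PET is analysed
unfiltered. MRI volumes are resliced to 1 x 1 x 1 mm before filtering.

Both filters are linear and annihilate constant volumes; the DWT3 channel plus
the complementary reconstruction (every other subband) recomposes the input
exactly, which is used as a self-check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt
from scipy import ndimage

from .grids import LesionMask, VoxelGrid


def _reslice_array(
    values: np.ndarray,
    spacing: tuple[float, float, float],
    target_mm: float,
    order: int,
) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    shape = np.asarray(values.shape)
    # Preserve the node-to-node physical extent within one voxel.
    new_shape = np.maximum(1, np.floor((shape - 1) * spacing / target_mm + 1e-9).astype(int) + 1)
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(values.astype(float), coords, order=order, mode="nearest")
    return out.reshape(tuple(new_shape))


def reslice_isotropic(grid: VoxelGrid, target_mm: float = 1.0) -> VoxelGrid:
    """Trilinear resampling onto an isotropic lattice (default 1 mm)."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if all(abs(s - target_mm) < 1e-12 for s in grid.spacing_mm):
        return grid
    values = _reslice_array(grid.values, grid.spacing_mm, target_mm, order=1)
    return dataclasses.replace(
        grid, values=values, spacing_mm=(target_mm,) * 3
    )


def reslice_mask(mask: LesionMask, target_mm: float = 1.0) -> LesionMask:
    """Nearest-neighbour companion path for masks."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if all(abs(s - target_mm) < 1e-12 for s in mask.spacing_mm):
        return mask
    support = _reslice_array(mask.support.astype(float), mask.spacing_mm, target_mm, order=0)
    return LesionMask(support > 0.5, (target_mm,) * 3, source=mask.source)


def log_kernel(sigma_px: float = 0.5, size: int = 5) -> np.ndarray:
    """Discrete 2-D Laplacian-of-Gaussian kernel, mean-subtracted to zero sum.

    Sampled from the analytic LoG
    ``(x^2 + y^2 - 2 sigma^2) / (2 pi sigma^6) * exp(-(x^2+y^2)/(2 sigma^2))``
    on a size x size grid centred at the origin.
    """
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    half = size // 2
    x, y = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    r2 = x**2 + y**2
    s2 = sigma_px**2
    kernel = (r2 - 2 * s2) / (2 * np.pi * s2**3) * np.exp(-r2 / (2 * s2))
    return kernel - kernel.mean()


def log_filter(grid: VoxelGrid, sigma_mm: float = 0.5, kernel_px: int = 5) -> VoxelGrid:
    """Per-axial-slice LoG filtering (reflect boundary); channel tag ``LoG``.

    Requires an isotropic 1 mm grid so sigma in mm equals sigma in pixels.
    """
    if any(abs(s - 1.0) > 1e-9 for s in grid.spacing_mm):
        raise ValueError("log_filter expects a 1 mm isotropic grid; reslice first")
    if kernel_px > min(grid.shape[0], grid.shape[1]):
        raise ValueError("LoG kernel larger than the axial slice")
    kernel = log_kernel(sigma_mm, kernel_px)
    out = np.empty_like(grid.values)
    for k in range(grid.shape[2]):  # third axis = slice index
        out[:, :, k] = ndimage.convolve(grid.values[:, :, k], kernel, mode="reflect")
    return grid.with_values(out, channel="LoG")


def dwt3_highpass(grid: VoxelGrid, wavelet: str = "coif1", mode: str = "hhh") -> VoxelGrid:
    """High-frequency reconstruction of a one-level 3-D wavelet decomposition.

    ``mode='hhh'`` (default) keeps only the subband that is high-pass along all
    three axes; ``mode='not_lll'`` keeps every detail subband (all except the
    approximation). Output shape equals input shape; channel tag ``DWT3``.
    """
    if mode not in ("hhh", "not_lll"):
        raise ValueError(f"unknown DWT3 mode {mode!r}")
    wav = pywt.Wavelet(wavelet)
    if min(grid.shape) < wav.dec_len:
        raise ValueError(
            f"volume axes {grid.shape} shorter than the {wavelet} filter ({wav.dec_len})"
        )
    coeffs = pywt.dwtn(grid.values, wav, mode="symmetric")
    keep = {"ddd"} if mode == "hhh" else {k for k in coeffs if k != "aaa"}
    kept = {k: (c if k in keep else np.zeros_like(c)) for k, c in coeffs.items()}
    recon = pywt.idwtn(kept, wav, mode="symmetric")
    recon = recon[tuple(slice(0, n) for n in grid.shape)]
    return grid.with_values(recon, channel="DWT3")


def dwt3_complement(grid: VoxelGrid, wavelet: str = "coif1") -> np.ndarray:
    """Reconstruction from every subband except HHH (perfect-reconstruction check)."""
    wav = pywt.Wavelet(wavelet)
    coeffs = pywt.dwtn(grid.values, wav, mode="symmetric")
    kept = {k: (np.zeros_like(c) if k == "ddd" else c) for k, c in coeffs.items()}
    recon = pywt.idwtn(kept, wav, mode="symmetric")
    return recon[tuple(slice(0, n) for n in grid.shape)]


def mri_channels(
    grid: VoxelGrid,
    channels: tuple[str, ...] = ("unfiltered", "LoG", "DWT3"),
    target_mm: float = 1.0,
    dwt3_mode: str = "hhh",
) -> dict[str, VoxelGrid]:
    """Reslice an MRI grid to isotropic resolution and produce the filter channels."""
    if grid.modality != "T1CE":
        raise ValueError("filter channels are defined for T1CE MRI only")
    iso = reslice_isotropic(grid, target_mm)
    out: dict[str, VoxelGrid] = {}
    for channel in channels:
        if channel == "unfiltered":
            out[channel] = iso
        elif channel == "LoG":
            out[channel] = log_filter(iso)
        elif channel == "DWT3":
            out[channel] = dwt3_highpass(iso, mode=dwt3_mode)
        else:
            raise ValueError(f"unknown channel {channel!r}")
    return out
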