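"""Synthetic paired PET / CE-MRI lesion phantoms.

Emulates the two lesion classes of the clinical problem — recurrent brain
metastasis versus radiation injury — as 3-D digital phantoms born co-registered:
a contrast-enhancing lesion on T1CE MRI and the same lesion with elevated
amino-acid uptake on PET. The classes differ in three controllable respects,
mirroring the qualitative contrast reported for real lesions: recurrences are
more heterogeneous in intensity, less spherical, and show higher PET
tumor-to-brain ratio (TBR).

Construction of a case:

* geometry — a sphere of nominal radius ``lesion_radius_mm`` whose boundary
  radius is modulated per direction by a random low-order (l = 2..4) real
  spherical-harmonic field scaled by ``shape_irregularity`` (0 = perfect ball;
  1 = up to +/-50% radial excursion); the support is reduced to its largest
  26-connected component so every lesion is a single blob;
* texture — a multiplicative stationary Gaussian random field inside the
  lesion: Gaussian-smoothed white noise with correlation length
  ``texture_corr_len_mm``, standardised, clipped at 3 SD and scaled so the
  multiplier is ``1 + texture_amp * g`` with ``g`` in [-1, 1] (``texture_amp
  < 1`` keeps intensities positive);
* intensity — PET lesion plateau at ``tbr_target * background_pet``; MRI
  lesion plateau at ``mri_contrast * background_mri``; additive Gaussian noise
  per modality on top.

All randomness is drawn from a per-case seed derived deterministically from
``spec.seed`` and the case id, so a case is a pure function of
(spec, label, case_id).
"""

from __future__ import annotations

import csv
import dataclasses
import zlib
from pathlib import Path

import numpy as np
from scipy import ndimage, special

from .grids import LesionMask, VoxelGrid, read_grid, read_mask, write_grid, write_mask

LABELS = ("recurrence", "injury")

#: Fraction of the nominal radius reached by the boundary perturbation at
#: shape_irregularity = 1.
_MAX_RADIAL_EXCURSION = 0.5


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort; defaults define the study conditions."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_pet: float = 1.0
    background_mri: float = 100.0
    noise_sd_pet: float = 0.05
    noise_sd_mri: float = 5.0
    lesion_radius_mm: float = 8.0
    shape_irregularity: float = 0.15
    texture_corr_len_mm: float = 2.0
    texture_amp: float = 0.2
    pet_texture_amp: float | None = None  # None: same as texture_amp
    tbr_target: float = 2.0
    mri_contrast: float = 2.0
    # per-case biological variability (SD of the per-case parameter draws)
    lesion_radius_sd_mm: float = 1.5
    shape_irregularity_sd: float = 0.10
    texture_amp_sd: float = 0.10
    tbr_sd: float = 0.35
    class_params: dict = dataclasses.field(
        default_factory=lambda: {
            "recurrence": {
                "shape_irregularity": 0.30,
                "texture_amp": 0.40,
                "pet_texture_amp": 0.30,
                "tbr_target": 2.5,
            },
            "injury": {
                "shape_irregularity": 0.18,
                "texture_amp": 0.18,
                "pet_texture_amp": 0.20,
                "tbr_target": 2.0,
            },
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if any(s < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not 0.0 <= self.texture_amp < 1.0:
            raise ValueError("texture_amp must lie in [0, 1)")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must lie in [0, 1]")
        missing = set(LABELS) - set(self.class_params)
        if missing:
            raise ValueError(f"class_params missing labels: {sorted(missing)}")

    def for_label(self, label: str) -> "PhantomSpec":
        """Spec with the per-class overrides of `label` applied."""
        if label not in LABELS:
            raise ValueError(f"unknown class label {label!r}")
        return dataclasses.replace(self, **self.class_params[label])


@dataclasses.dataclass(frozen=True)
class PatientCase:
    """One synthetic patient: co-registered PET + MRI, MRI mask, ground-truth label."""

    case_id: str
    pet: VoxelGrid
    mri: VoxelGrid
    mri_mask: LesionMask
    pet_background: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.pet.shape != self.mri.shape or self.pet.spacing_mm != self.mri.spacing_mm:
            raise ValueError("PET and MRI grids must share shape and spacing")
        if self.mri_mask.n_voxels < 1:
            raise ValueError("lesion mask is empty")


def case_seed(spec_seed: int, case_id: str) -> int:
    """Deterministic 31-bit per-case seed."""
    return zlib.crc32(f"{spec_seed}:{case_id}".encode()) & 0x7FFFFFFF


def _harmonic_coefficients(rng: np.random.Generator) -> np.ndarray:
    """Coefficients for the real spherical harmonics of degrees 2..4 (21 terms)."""
    return rng.standard_normal(21)


def _radial_harmonic_field(
    theta: np.ndarray, phi: np.ndarray, coeffs: np.ndarray
) -> np.ndarray:
    """Real spherical-harmonic sum over degrees 2..4, unit-RMS, clipped to [-1, 1]."""
    field = np.zeros_like(theta)
    k = 0
    for ell in range(2, 5):
        for m in range(0, ell + 1):
            y = special.sph_harm_y(ell, m, theta, phi)
            field += coeffs[k] * y.real
            k += 1
            if m > 0:
                field += coeffs[k] * y.imag
                k += 1
    rms = np.sqrt(np.mean(field**2))
    if rms > 0:
        field = field / rms
    return np.clip(field, -2.0, 2.0) / 2.0


def _texture_multiplier(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    corr_len_mm: float,
    amp: float,
    rng: np.random.Generator,
    support: np.ndarray,
) -> np.ndarray:
    """1 + amp * g with g a smoothed, standardised random field (computed on
    the lesion bounding box only; outside the lesion the multiplier is unused)."""
    if amp == 0.0:
        return np.ones(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    margin = int(np.ceil(4 * max(sigma_vox)))
    idx = np.nonzero(support)
    lo = [max(0, int(i.min()) - margin) for i in idx]
    hi = [min(n, int(i.max()) + 1 + margin) for i, n in zip(idx, shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    white = rng.standard_normal(tuple(b - a for a, b in zip(lo, hi)))
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    inside = smooth[support[box]]
    sd = inside.std()
    if sd == 0:
        return np.ones(shape)
    g = np.clip((smooth - inside.mean()) / (3.0 * sd), -1.0, 1.0)
    out = np.ones(shape)
    out[box] = 1.0 + amp * g
    return out


def generate_case(spec: PhantomSpec, label: str, case_id: str) -> PatientCase:
    """Generate one synthetic case; bit-identical for identical (spec, label, case_id)."""
    p = spec.for_label(label)
    rng = np.random.default_rng(case_seed(spec.seed, case_id))

    # Per-case biological variability around the class means (clipped to the
    # generator's valid ranges). SDs of zero give exactly the class means.
    radius = float(
        np.clip(
            p.lesion_radius_mm + p.lesion_radius_sd_mm * rng.standard_normal(),
            3.0,
            1.5 * p.lesion_radius_mm,
        )
    )
    irregularity = float(
        np.clip(p.shape_irregularity + p.shape_irregularity_sd * rng.standard_normal(), 0.0, 0.8)
    )
    amp_mri = float(np.clip(p.texture_amp + p.texture_amp_sd * rng.standard_normal(), 0.0, 0.85))
    base_pet_amp = p.texture_amp if p.pet_texture_amp is None else p.pet_texture_amp
    amp_pet = float(np.clip(base_pet_amp + p.texture_amp_sd * rng.standard_normal(), 0.0, 0.85))
    tbr = max(1.3, p.tbr_target + p.tbr_sd * rng.standard_normal())
    p = dataclasses.replace(
        spec.for_label(label),
        lesion_radius_mm=radius,
        shape_irregularity=irregularity,
        texture_amp=amp_mri,
        pet_texture_amp=amp_pet,
        tbr_target=tbr,
    )

    shape = p.grid_shape
    spacing = np.asarray(p.spacing_mm)
    center = (np.asarray(shape) - 1) / 2.0 * spacing

    r_max = p.lesion_radius_mm * (1.0 + _MAX_RADIAL_EXCURSION * p.shape_irregularity)
    half_extent = (np.asarray(shape) - 1) / 2.0 * spacing
    if np.any(r_max >= half_extent):
        raise ValueError(
            f"lesion radius {p.lesion_radius_mm} mm (max excursion {r_max:.1f} mm) "
            f"does not fit grid of half-extent {half_extent.min():.1f} mm"
        )

    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    # Fixed RNG draw order regardless of irregularity so streams stay comparable.
    coeffs = _harmonic_coefficients(rng)
    support = dist <= p.lesion_radius_mm
    if p.shape_irregularity > 0:
        # Only the shell between the inner and outer excursion radii can flip,
        # so the harmonics are evaluated there alone.
        excursion = _MAX_RADIAL_EXCURSION * p.shape_irregularity * p.lesion_radius_mm
        shell = (dist > p.lesion_radius_mm - excursion) & (dist <= p.lesion_radius_mm + excursion)
        idx = np.nonzero(shell)
        d = dist[idx]
        if len(d) > 0:  # excursion can be smaller than the voxel pitch
            dx, dy, dz = (axes[a][idx[a]] for a in range(3))
            theta = np.arccos(np.clip(dz / d, -1, 1))
            phi = np.arctan2(dy, dx) % (2 * np.pi)
            harmonic = _radial_harmonic_field(theta, phi, coeffs)
            radius = p.lesion_radius_mm + excursion * harmonic
            support = dist <= p.lesion_radius_mm - excursion
            support[idx] = d <= radius
    labels, n_comp = ndimage.label(support, structure=np.ones((3, 3, 3), dtype=int))
    if n_comp == 0:
        raise ValueError("lesion support is empty")
    if n_comp > 1:
        sizes = ndimage.sum_labels(support, labels, index=np.arange(1, n_comp + 1))
        support = labels == (1 + int(np.argmax(sizes)))

    mult_pet = _texture_multiplier(
        shape, p.spacing_mm, p.texture_corr_len_mm, p.pet_texture_amp, rng, support
    )
    mult_mri = _texture_multiplier(
        shape, p.spacing_mm, p.texture_corr_len_mm, p.texture_amp, rng, support
    )

    pet = np.full(shape, float(p.background_pet))
    pet[support] = (p.tbr_target * p.background_pet * mult_pet)[support]
    mri = np.full(shape, float(p.background_mri))
    mri[support] = (p.mri_contrast * p.background_mri * mult_mri)[support]

    if p.noise_sd_pet > 0:
        pet = pet + p.noise_sd_pet * rng.standard_normal(shape)
    if p.noise_sd_mri > 0:
        mri = mri + p.noise_sd_mri * rng.standard_normal(shape)

    return PatientCase(
        case_id=case_id,
        pet=VoxelGrid(pet, p.spacing_mm, modality="PET"),
        mri=VoxelGrid(mri, p.spacing_mm, modality="T1CE"),
        mri_mask=LesionMask(support, p.spacing_mm, source="manual_mri"),
        pet_background=float(p.background_pet),
        label=label,
    )


def generate_cohort(n: int, prevalence: float, spec: PhantomSpec) -> list[PatientCase]:
    """Cohort with exactly round-half-up(n * prevalence) recurrence cases."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    n_recurrence = int(np.floor(n * prevalence + 0.5))
    cases = []
    for i in range(n):
        label = "recurrence" if i < n_recurrence else "injury"
        cases.append(generate_case(spec, label, f"case_{i:03d}"))
    return cases


def write_case(case: PatientCase, directory: str | Path) -> dict[str, Path]:
    """Serialise a case to NIfTI; the directory must already exist."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {
        "pet": write_grid(case.pet, directory / f"{case.case_id}_pet.nii.gz"),
        "mri": write_grid(case.mri, directory / f"{case.case_id}_mri.nii.gz"),
        "mask": write_mask(case.mri_mask, directory / f"{case.case_id}_mask.nii.gz"),
    }
    return paths


def read_case(directory: str | Path, case_id: str, label: str, pet_background: float) -> PatientCase:
    directory = Path(directory)
    return PatientCase(
        case_id=case_id,
        pet=read_grid(directory / f"{case_id}_pet.nii.gz", modality="PET"),
        mri=read_grid(directory / f"{case_id}_mri.nii.gz", modality="T1CE"),
        mri_mask=read_mask(directory / f"{case_id}_mask.nii.gz"),
        pet_background=pet_background,
        label=label,
    )


def write_cohort(cases: list[PatientCase], directory: str | Path) -> Path:
    """Write every case plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "pet", "mri", "mask", "pet_background"])
        for case in cases:
            paths = write_case(case, directory)
            writer.writerow(
                [case.case_id, case.label, paths["pet"].name, paths["mri"].name,
                 paths["mask"].name, case.pet_background]
            )
    return manifest


def read_cohort(manifest: str | Path) -> list[PatientCase]:
    manifest = Path(manifest)
    directory = manifest.parent
    cases = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            cases.append(
                read_case(directory, row["case_id"], row["label"], float(row["pet_background"]))
            )
    return cases
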