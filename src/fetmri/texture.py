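"""Grey-level quantization and the 42 radiomic features per image channel.

The feature set mirrors the LIFEx texture families computed on a 3-D VOI:

* 5 conventional statistics: Min, Mean, Max, SD of the raw VOI intensities and
  the VOI volume in mL;
* 4 first-order histogram features on the 64-bin quantized distribution:
  skewness, kurtosis (plain standardised 4th moment), entropy (log2), energy;
* 31 second-order features from four matrices built on the quantized VOI —
  GLCM (6), GLRLM (11), NGLDM (3), GLZLM (11);
* 2 shape indices: sphericity and compacity from a triangulated isosurface.

Quantization maps VOI intensities to levels 1..G (G = 64) between
``mean - 3 SD`` and ``mean + 3 SD`` of the in-VOI intensities (population SD),
``g = 1 + floor(G (v - lower) / (upper - lower))`` clamped to [1, G].

All pairwise/run statistics use the 13 unique distance-1 lattice directions;
zones and NGLDM neighbourhoods use 26-connectivity. Entropies are log base 2.
Features that are undefined on degenerate VOIs (e.g. GLCM correlation when the
level variance is zero) are reported as 0 and listed in the returned flags.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import LesionMask, VoxelGrid

#: 13 unique 3-D lattice directions at Chebyshev distance 1 (half of the 26).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_EPS_COARSENESS = 1e-6

STATISTICAL_NAMES = ("Min", "Mean", "Max", "SD", "Volume")
HISTOGRAM_NAMES = ("HISTO_Skewness", "HISTO_Kurtosis", "HISTO_Entropy", "HISTO_Energy")
GLCM_NAMES = (
    "GLCM_Homogeneity", "GLCM_Energy", "GLCM_Contrast",
    "GLCM_Correlation", "GLCM_Entropy", "GLCM_Dissimilarity",
)
GLRLM_NAMES = (
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNUr", "RLNU", "RP",
)
NGLDM_NAMES = ("NGLDM_Coarseness", "NGLDM_Contrast", "NGLDM_Busyness")
GLZLM_NAMES = (
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNUz", "ZLNU", "ZP",
)
SECOND_ORDER_NAMES = GLCM_NAMES + GLRLM_NAMES + NGLDM_NAMES + GLZLM_NAMES
SHAPE_NAMES = ("Sphericity", "Compacity")

#: The 42 feature base names, partitioned 5 / 4 / 31 / 2.
FEATURE_NAMES = STATISTICAL_NAMES + HISTOGRAM_NAMES + SECOND_ORDER_NAMES + SHAPE_NAMES

#: Channel name -> column prefix.
CHANNEL_PREFIXES = {
    "T1": "T1_",
    "T1_LoG": "T1_LoG_",
    "T1_DWT3": "T1_DWT3_",
    "PET": "PET_",
}


@dataclasses.dataclass(frozen=True)
class QuantizedVOI:
    """VOI voxels mapped to integer grey levels 1..G on a cropped lattice.

    ``levels`` is 0 outside the mask and in 1..G inside.
    """

    levels: np.ndarray
    mask: np.ndarray
    G: int
    lower: float
    upper: float
    degenerate: bool

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _crop_to_mask(values: np.ndarray, support: np.ndarray, margin: int = 1):
    idx = np.nonzero(support)
    lo = [max(0, int(i.min()) - margin) for i in idx]
    hi = [min(n, int(i.max()) + 1 + margin) for i, n in zip(idx, support.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[box], support[box]


def quantize(grid: VoxelGrid, mask: LesionMask, G: int = 64, population_sd: bool = True) -> QuantizedVOI:
    """Rescale in-VOI intensities to G bins between mean -/+ 3 SD."""
    if mask.n_voxels == 0:
        raise ValueError("cannot quantize an empty VOI")
    if grid.shape != mask.shape:
        raise ValueError("grid and mask are not aligned")
    values, support = _crop_to_mask(grid.values, mask.support)
    inside = values[support]
    mean = inside.mean()
    sd = inside.std(ddof=0 if population_sd else 1)
    lower, upper = mean - 3 * sd, mean + 3 * sd
    levels = np.zeros(values.shape, dtype=np.int32)
    if sd == 0:
        levels[support] = 1
        return QuantizedVOI(levels, support, G, lower, upper, degenerate=True)
    g = 1 + np.floor(G * (values - lower) / (upper - lower))
    levels[support] = np.clip(g[support], 1, G).astype(np.int32)
    return QuantizedVOI(levels, support, G, float(lower), float(upper), degenerate=False)


def conventional_stats(grid: VoxelGrid, mask: LesionMask, population_sd: bool = True) -> dict[str, float]:
    """Min/Mean/Max/SD of raw VOI intensities and VOI volume in mL."""
    if mask.n_voxels == 0:
        raise ValueError("empty VOI")
    inside = grid.values[mask.support]
    return {
        "Min": float(inside.min()),
        "Mean": float(inside.mean()),
        "Max": float(inside.max()),
        "SD": float(inside.std(ddof=0 if population_sd else 1)),
        "Volume": float(mask.n_voxels * mask.voxel_volume_mm3 / 1000.0),
    }


def histogram_features(q: QuantizedVOI) -> tuple[dict[str, float], dict[str, str]]:
    """Skewness, kurtosis, entropy (bits) and energy of the G-bin histogram."""
    counts = np.bincount(q.in_mask_levels, minlength=q.G + 1)[1:]
    h = counts / counts.sum()
    levels = np.arange(1, q.G + 1, dtype=float)
    mu = float(h @ levels)
    var = float(h @ (levels - mu) ** 2)
    nz = h[h > 0]
    entropy = float(-(nz @ np.log2(nz)))
    energy = float(nz @ nz)
    flags: dict[str, str] = {}
    if var == 0:
        flags["HISTO_Skewness"] = "undefined: zero variance"
        flags["HISTO_Kurtosis"] = "undefined: zero variance"
        skew = kurt = 0.0
    else:
        sd = np.sqrt(var)
        skew = float(h @ ((levels - mu) / sd) ** 3)
        kurt = float(h @ ((levels - mu) / sd) ** 4)
    return (
        {"HISTO_Skewness": skew, "HISTO_Kurtosis": kurt,
         "HISTO_Entropy": entropy, "HISTO_Energy": energy},
        flags,
    )


# ---------------------------------------------------------------------------
# GLCM

def _direction_slices(d, shape):
    s1, s2 = [], []
    for delta, n in zip(d, shape):
        if delta >= 0:
            s1.append(slice(0, n - delta))
            s2.append(slice(delta, n))
        else:
            s1.append(slice(-delta, n))
            s2.append(slice(0, n + delta))
    return tuple(s1), tuple(s2)


def build_glcm(q: QuantizedVOI) -> np.ndarray:
    """Symmetric co-occurrence probabilities pooled over the 13 directions."""
    counts = np.zeros((q.G, q.G))
    for d in DIRECTIONS_13:
        s1, s2 = _direction_slices(d, q.levels.shape)
        valid = q.mask[s1] & q.mask[s2]
        i = q.levels[s1][valid] - 1
        j = q.levels[s2][valid] - 1
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-VOI voxel pairs at distance 1")
    return counts / total


def glcm_features(p: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=float)[:, None]
    j = np.arange(1, G + 1, dtype=float)[None, :]
    diff = np.abs(i - j)
    homogeneity = float((p / (1.0 + diff)).sum())
    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    dissimilarity = float((diff * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    flags: dict[str, str] = {}
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
        flags["GLCM_Correlation"] = "undefined: zero marginal variance"
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return (
        {"GLCM_Homogeneity": homogeneity, "GLCM_Energy": energy,
         "GLCM_Contrast": contrast, "GLCM_Correlation": correlation,
         "GLCM_Entropy": entropy, "GLCM_Dissimilarity": dissimilarity},
        flags,
    )


# ---------------------------------------------------------------------------
# GLRLM

def build_glrlm(q: QuantizedVOI) -> np.ndarray:
    """Run counts r[i-1, l-1] over maximal runs along the 13 directions."""
    shape = q.levels.shape
    max_len = int(np.ceil(np.sqrt(sum(n**2 for n in shape)))) + 1
    counts = np.zeros((q.G, max_len))
    for d in DIRECTIONS_13:
        s1, s2 = _direction_slices(d, shape)
        cont = np.zeros(shape, dtype=bool)  # cont[x]: run continues from x to x+d
        cont[s1] = q.mask[s1] & q.mask[s2] & (q.levels[s1] == q.levels[s2])
        prev = np.zeros(shape, dtype=bool)  # prev[x]: x continues a run from x-d
        prev[s2] = cont[s1]
        starts = q.mask & ~prev
        pos = np.argwhere(starts)
        level = q.levels[starts]
        length = np.ones(len(pos), dtype=int)
        active = np.ones(len(pos), dtype=bool)
        cur = pos.copy()
        while active.any():
            idx = cur[active]
            go_on = cont[idx[:, 0], idx[:, 1], idx[:, 2]]
            upd = np.where(active)[0][go_on]
            length[upd] += 1
            cur[upd] += d
            active[np.where(active)[0][~go_on]] = False
        np.add.at(counts, (level - 1, length - 1), 1.0)
    return counts[:, : max(1, int(np.max(np.nonzero(counts.sum(axis=0))[0])) + 1)]


def _run_zone_features(matrix: np.ndarray, n_voxels: int, kind: str) -> dict[str, float]:
    """Shared emphasis/non-uniformity formulas for GLRLM (runs) and GLZLM (zones)."""
    total = matrix.sum()
    i = np.arange(1, matrix.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, matrix.shape[1] + 1, dtype=float)[None, :]
    short = float((matrix / l**2).sum()) / total
    long_ = float((matrix * l**2).sum()) / total
    low = float((matrix / i**2).sum()) / total
    high = float((matrix * i**2).sum()) / total
    short_low = float((matrix / (i**2 * l**2)).sum()) / total
    short_high = float((matrix * i**2 / l**2).sum()) / total
    long_low = float((matrix * l**2 / i**2).sum()) / total
    long_high = float((matrix * i**2 * l**2).sum()) / total
    glnu = float((matrix.sum(axis=1) ** 2).sum()) / total
    lnu = float((matrix.sum(axis=0) ** 2).sum()) / total
    if kind == "run":
        names = GLRLM_NAMES
        pct = total / (len(DIRECTIONS_13) * n_voxels)
    else:
        names = GLZLM_NAMES
        pct = total / n_voxels
    vals = (short, long_, low, high, short_low, short_high, long_low, long_high,
            glnu, lnu, float(pct))
    return dict(zip(names, vals))


def glrlm_features(matrix: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(matrix, n_voxels, "run")


# ---------------------------------------------------------------------------
# NGLDM

def build_ngldm(q: QuantizedVOI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level probabilities p_i, dissimilarity sums s_i and contributor count.

    For every VOI voxel with at least one in-VOI 26-neighbour the absolute
    difference between its level and the mean level of those neighbours is
    accumulated; voxels without in-VOI neighbours are skipped.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = q.mask.astype(float)
    neigh_sum = ndimage.convolve(q.levels * m, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    contributing = q.mask & (neigh_cnt > 0.5)
    levels = q.levels[contributing]
    abar = neigh_sum[contributing] / neigh_cnt[contributing]
    diff = np.abs(levels - abar)
    s = np.zeros(q.G)
    np.add.at(s, levels - 1, diff)
    n = np.bincount(levels - 1, minlength=q.G).astype(float)
    n_contrib = int(contributing.sum())
    p = n / n_contrib if n_contrib else n
    return p, s, n_contrib


def ngldm_features(
    p: np.ndarray, s: np.ndarray, n_contrib: int
) -> tuple[dict[str, float], dict[str, str]]:
    occupied = np.nonzero(p > 0)[0]
    levels = occupied + 1.0
    coarseness = float(1.0 / (_EPS_COARSENESS + (p * s).sum()))
    flags: dict[str, str] = {}
    if len(occupied) < 2:
        flags["NGLDM_Contrast"] = "undefined: fewer than 2 occupied levels"
        flags["NGLDM_Busyness"] = "undefined: fewer than 2 occupied levels"
        return (
            {"NGLDM_Coarseness": coarseness, "NGLDM_Contrast": 0.0, "NGLDM_Busyness": 0.0},
            flags,
        )
    po = p[occupied]
    n_g = len(occupied)
    pair = float((po[:, None] * po[None, :] * (levels[:, None] - levels[None, :]) ** 2).sum())
    contrast = pair / (n_g * (n_g - 1)) * float(s.sum()) / n_contrib
    ip = levels * po
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())  # i != j terms; diagonal is 0
    busyness = float((p * s).sum()) / denom if denom > 0 else 0.0
    if denom == 0:
        flags["NGLDM_Busyness"] = "undefined: zero weighted-level differences"
    return (
        {"NGLDM_Coarseness": coarseness, "NGLDM_Contrast": contrast, "NGLDM_Busyness": busyness},
        flags,
    )


# ---------------------------------------------------------------------------
# GLZLM

def build_glzlm(q: QuantizedVOI) -> np.ndarray:
    """Zone counts z[i-1, s-1]: 26-connected components of equal grey level."""
    structure = np.ones((3, 3, 3), dtype=int)
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in np.unique(q.in_mask_levels):
        labels, n_comp = ndimage.label(q.levels == level, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        sizes_by_level.append((int(level), sizes))
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((q.G, max_size))
    for level, sizes in sizes_by_level:
        np.add.at(counts, (level - 1, sizes - 1), 1.0)
    return counts


def glzlm_features(matrix: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(matrix, n_voxels, "zone")


# ---------------------------------------------------------------------------
# Shape

def shape_features(mask: LesionMask) -> dict[str, float]:
    """Sphericity (36 pi V^2)^(1/3) / A and compacity V / (sqrt(pi) A^(3/2)).

    The surface area A comes from a triangulated isosurface (marching cubes),
    not from voxel-face counting, which would bias sphericity low. The mesh is
    extracted at the zero level of the signed Euclidean distance field of the
    mask, linearly upsampled 2x with mild smoothing: on flat axis-aligned
    faces this reproduces the analytic area almost exactly, and it softens the
    corner chamfering of meshes built directly on binary lattices.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    support, _ = _crop_to_mask(mask.support.astype(float), mask.support, margin=2)
    support = np.pad(support > 0.5, 1)  # guarantee a closed surface
    sampling = mask.spacing_mm
    signed = ndimage.distance_transform_edt(support, sampling=sampling) - ndimage.distance_transform_edt(
        ~support, sampling=sampling
    )
    fine = ndimage.zoom(signed, 2, order=1)
    fine = ndimage.gaussian_filter(fine, 0.5)
    half_spacing = tuple(s / 2.0 for s in mask.spacing_mm)
    verts, faces, _, _ = measure.marching_cubes(fine, level=0.0, spacing=half_spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    volume = mask.n_voxels * mask.voxel_volume_mm3
    return {
        "Sphericity": float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area),
        "Compacity": float(volume / (np.sqrt(np.pi) * area**1.5)),
    }


# ---------------------------------------------------------------------------
# Full per-channel vector

def extract_features(
    grid: VoxelGrid, mask: LesionMask, G: int = 64, population_sd: bool = True
) -> tuple[dict[str, float], dict[str, str]]:
    """The 42 named features of one channel's VOI, plus undefined-value flags."""
    features = conventional_stats(grid, mask, population_sd=population_sd)
    q = quantize(grid, mask, G=G, population_sd=population_sd)
    flags: dict[str, str] = {}
    if q.degenerate:
        flags["quantization"] = "degenerate: zero intensity SD"

    hist, f = histogram_features(q)
    features.update(hist)
    flags.update(f)

    glcm, f = glcm_features(build_glcm(q))
    features.update(glcm)
    flags.update(f)

    features.update(glrlm_features(build_glrlm(q), q.n_voxels))

    ngldm, f = ngldm_features(*build_ngldm(q))
    features.update(ngldm)
    flags.update(f)

    features.update(glzlm_features(build_glzlm(q), q.n_voxels))
    features.update(shape_features(mask))

    assert set(features) == set(FEATURE_NAMES) and len(features) == 42
    return features, flags


def extract_all(
    case,
    channels: tuple[str, ...] = ("T1", "T1_LoG", "T1_DWT3", "PET"),
    G: int = 64,
    tbr_threshold: float = 1.6,
    connectivity: int = 26,
    min_voxels: int = 100,
    target_mm: float = 1.0,
    dwt3_mode: str = "hhh",
    reslice_pet: bool = False,
) -> tuple[dict[str, float], dict[str, str], dict[str, str]]:
    """All requested channels of one case.

    MRI channels (T1, T1_LoG, T1_DWT3) are computed on the 1 mm-resliced MRI
    with the (resliced) manual MRI mask. The PET channel uses the TBR
    auto-contour; a PET-negative lesion falls back to the MRI mask transferred
    onto the PET lattice. Channels whose VOI fails the 100-voxel rule are
    skipped and the cause recorded.

    Returns (features, flags, exclusions) where feature names carry the
    channel prefixes (``T1_``, ``T1_LoG_``, ``T1_DWT3_``, ``PET_``).
    """
    from . import imageprep, voi as voi_mod

    unknown = set(channels) - set(CHANNEL_PREFIXES)
    if unknown:
        raise ValueError(
            f"unknown channels {sorted(unknown)}; PET is analysed unfiltered only"
        )
    features: dict[str, float] = {}
    flags: dict[str, str] = {}
    exclusions: dict[str, str] = {}

    mri_wanted = [c for c in channels if c.startswith("T1")]
    if mri_wanted:
        filter_names = {"T1": "unfiltered", "T1_LoG": "LoG", "T1_DWT3": "DWT3"}
        grids = imageprep.mri_channels(
            case.mri,
            channels=tuple(filter_names[c] for c in mri_wanted),
            target_mm=target_mm,
            dwt3_mode=dwt3_mode,
        )
        mask = imageprep.reslice_mask(case.mri_mask, target_mm)
        if voi_mod.enforce_min_voxels(mask, min_voxels):
            for channel in mri_wanted:
                vec, fl = extract_features(grids[filter_names[channel]], mask, G=G)
                prefix = CHANNEL_PREFIXES[channel]
                features.update({prefix + k: v for k, v in vec.items()})
                flags.update({prefix + k: v for k, v in fl.items()})
        else:
            for channel in mri_wanted:
                exclusions[channel] = f"MRI VOI below {min_voxels} voxels"

    if "PET" in channels:
        pet = imageprep.reslice_isotropic(case.pet, target_mm) if reslice_pet else case.pet
        params = voi_mod.TbrParams(
            background=case.pet_background,
            threshold_ratio=tbr_threshold,
            connectivity=connectivity,
        )
        pet_mask = voi_mod.autocontour_pet(pet, params)
        if pet_mask.n_voxels == 0:
            pet_mask = voi_mod.transfer_mask(case.mri_mask, pet)
            flags["PET_voi"] = "PET-negative: transferred MRI VOI"
        if voi_mod.enforce_min_voxels(pet_mask, min_voxels):
            vec, fl = extract_features(pet, pet_mask, G=G)
            features.update({"PET_" + k: v for k, v in vec.items()})
            flags.update({"PET_" + k: v for k, v in fl.items()})
        else:
            exclusions["PET"] = f"PET VOI below {min_voxels} voxels"

    return features, flags, exclusions


def feature_columns(channels: tuple[str, ...] = ("T1", "T1_LoG", "T1_DWT3", "PET")) -> list[str]:
    """Ordered column names: 42 features per channel, channel-major."""
    return [CHANNEL_PREFIXES[c] + name for c in channels for name in FEATURE_NAMES]


def build_feature_table(
    cases,
    channels: tuple[str, ...] = ("T1", "T1_LoG", "T1_DWT3", "PET"),
    **kwargs,
):
    """Cases x features table (pandas DataFrame) with a ``label`` column.

    Excluded channels leave NaN in their columns; exclusion causes are
    collected in the returned exclusion log (case_id -> channel -> cause).
    """
    import pandas as pd

    columns = feature_columns(channels)
    rows, labels, index = [], [], []
    exclusion_log: dict[str, dict[str, str]] = {}
    for case in cases:
        vec, _, excl = extract_all(case, channels=channels, **kwargs)
        rows.append([vec.get(c, np.nan) for c in columns])
        labels.append(case.label)
        index.append(case.case_id)
        if excl:
            exclusion_log[case.case_id] = excl
    table = pd.DataFrame(rows, columns=columns, index=pd.Index(index, name="case_id"))
    table["label"] = labels
    return table, exclusion_log
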