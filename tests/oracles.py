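"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plainly as possible (python loops, explicit
enumeration) and never calls the package's own texture/matrix code, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def brute_glcm(levels: np.ndarray, mask: np.ndarray, G: int) -> np.ndarray:
    counts = np.zeros((G, G))
    voxels = list(zip(*np.nonzero(mask)))
    for v in voxels:
        for d in OFFSETS_13:
            w = tuple(a + b for a, b in zip(v, d))
            if _in(mask.shape, w) and mask[w]:
                i, j = levels[v] - 1, levels[w] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    return counts / counts.sum()


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    G = p.shape[0]
    homog = energy = contrast = entropy = dissim = 0.0
    mu_i = mu_j = 0.0
    for i in range(G):
        for j in range(G):
            if p[i, j] == 0:
                continue
            gi, gj = i + 1, j + 1
            homog += p[i, j] / (1 + abs(gi - gj))
            energy += p[i, j] ** 2
            contrast += (gi - gj) ** 2 * p[i, j]
            dissim += abs(gi - gj) * p[i, j]
            entropy -= p[i, j] * math.log2(p[i, j])
            mu_i += gi * p[i, j]
            mu_j += gj * p[i, j]
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(G) for j in range(G))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    if var_i > 0 and var_j > 0:
        corr = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j] for i in range(G) for j in range(G)
        ) / math.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return {
        "GLCM_Homogeneity": homog, "GLCM_Energy": energy, "GLCM_Contrast": contrast,
        "GLCM_Correlation": corr, "GLCM_Entropy": entropy, "GLCM_Dissimilarity": dissim,
    }


def brute_runs(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(grey level, run length) for every maximal run along the 13 directions."""
    runs = []
    for d in OFFSETS_13:
        for v in zip(*np.nonzero(mask)):
            prev = tuple(a - b for a, b in zip(v, d))
            if _in(mask.shape, prev) and mask[prev] and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            cur = v
            while True:
                nxt = tuple(a + b for a, b in zip(cur, d))
                if _in(mask.shape, nxt) and mask[nxt] and levels[nxt] == levels[v]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((int(levels[v]), length))
    return runs


def brute_glrlm_features(levels, mask, n_voxels) -> dict[str, float]:
    runs = brute_runs(levels, mask)
    nr = len(runs)
    feats = {
        "SRE": sum(1 / l**2 for _, l in runs) / nr,
        "LRE": sum(l**2 for _, l in runs) / nr,
        "LGRE": sum(1 / i**2 for i, _ in runs) / nr,
        "HGRE": sum(i**2 for i, _ in runs) / nr,
        "SRLGE": sum(1 / (i**2 * l**2) for i, l in runs) / nr,
        "SRHGE": sum(i**2 / l**2 for i, l in runs) / nr,
        "LRLGE": sum(l**2 / i**2 for i, l in runs) / nr,
        "LRHGE": sum(i**2 * l**2 for i, l in runs) / nr,
        "RP": nr / (13 * n_voxels),
    }
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for i, l in runs:
        by_level[i] = by_level.get(i, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    feats["GLNUr"] = sum(c**2 for c in by_level.values()) / nr
    feats["RLNU"] = sum(c**2 for c in by_length.values()) / nr
    return feats


def brute_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(grey level, size) of each 26-connected equal-level zone (BFS)."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        level = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in OFFSETS_26:
                w = tuple(a + b for a, b in zip(v, d))
                if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == level:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(level), size))
    return zones


def brute_glzlm_features(levels, mask, n_voxels) -> dict[str, float]:
    zones = brute_zones(levels, mask)
    nz = len(zones)
    feats = {
        "SZE": sum(1 / s**2 for _, s in zones) / nz,
        "LZE": sum(s**2 for _, s in zones) / nz,
        "LGZE": sum(1 / i**2 for i, _ in zones) / nz,
        "HGZE": sum(i**2 for i, _ in zones) / nz,
        "SZLGE": sum(1 / (i**2 * s**2) for i, s in zones) / nz,
        "SZHGE": sum(i**2 / s**2 for i, s in zones) / nz,
        "LZLGE": sum(s**2 / i**2 for i, s in zones) / nz,
        "LZHGE": sum(i**2 * s**2 for i, s in zones) / nz,
        "ZP": nz / n_voxels,
    }
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for i, s in zones:
        by_level[i] = by_level.get(i, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    feats["GLNUz"] = sum(c**2 for c in by_level.values()) / nz
    feats["ZLNU"] = sum(c**2 for c in by_size.values()) / nz
    return feats


def brute_ngldm_features(levels, mask, eps=1e-6) -> dict[str, float]:
    per_level_s: dict[int, float] = {}
    per_level_n: dict[int, int] = {}
    n_contrib = 0
    for v in zip(*np.nonzero(mask)):
        neigh = [
            levels[tuple(a + b for a, b in zip(v, d))]
            for d in OFFSETS_26
            if _in(mask.shape, tuple(a + b for a, b in zip(v, d)))
            and mask[tuple(a + b for a, b in zip(v, d))]
        ]
        if not neigh:
            continue
        n_contrib += 1
        i = int(levels[v])
        per_level_s[i] = per_level_s.get(i, 0.0) + abs(i - sum(neigh) / len(neigh))
        per_level_n[i] = per_level_n.get(i, 0) + 1
    p = {i: n / n_contrib for i, n in per_level_n.items()}
    coarseness = 1.0 / (eps + sum(p[i] * per_level_s[i] for i in p))
    occupied = sorted(p)
    if len(occupied) < 2:
        return {"NGLDM_Coarseness": coarseness, "NGLDM_Contrast": 0.0, "NGLDM_Busyness": 0.0}
    ng = len(occupied)
    pair = sum(p[i] * p[j] * (i - j) ** 2 for i in occupied for j in occupied)
    contrast = pair / (ng * (ng - 1)) * sum(per_level_s.values()) / n_contrib
    denom = sum(abs(i * p[i] - j * p[j]) for i in occupied for j in occupied if i != j)
    busyness = sum(p[i] * per_level_s[i] for i in p) / denom if denom else 0.0
    return {"NGLDM_Coarseness": coarseness, "NGLDM_Contrast": contrast, "NGLDM_Busyness": busyness}


def brute_auc(scores, labels) -> float:
    """Concordant-pair counting with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def statsmodels_best_subset(X, y, pool, max_vars):
    """Exhaustive AIC search with statsmodels fits (ties: fewer vars, name order)."""
    import statsmodels.api as sm

    best = None
    for size in range(1, max_vars + 1):
        for combo in itertools.combinations(sorted(pool), size):
            design = sm.add_constant(np.asarray(X[list(combo)], dtype=float))
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100)
            if np.abs(fit.params[1:] * np.asarray(X[list(combo)]).std(axis=0)).max() > 15:
                continue  # separated
            aic = 2 * len(fit.params) - 2 * fit.llf
            if best is None or aic < best[0] - 1e-9:
                best = (aic, combo)
    return best
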