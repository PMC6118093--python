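"""Univariate Mann-Whitney screening and candidate-pool construction.

Each feature is tested for a distribution shift between the recurrence and
injury groups with a two-sided Mann-Whitney U test; features with p < alpha
(default 0.05, uncorrected — multiple-testing correction is available but off
by default) enter the candidate pools. The combined PET/MRI pool is the union
of the significant MRI features and the top-k (default 8) most significant
PET features.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "recurrence"
NEGATIVE_LABEL = "injury"


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    """Per-feature U statistic, two-sided p, and the selection flag."""

    table: pd.DataFrame  # index = feature, columns = U, p, selected
    alpha: float
    n1: int  # recurrence
    n2: int  # injury

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclasses.dataclass(frozen=True)
class CandidatePool:
    modality: str  # MRI | PET | combined
    features: tuple[str, ...]
    provenance: str

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in pool")


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the statistic of the first sample.

    Exact enumeration when n1 + n2 <= 12 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def screen_features(
    table: pd.DataFrame,
    modality: str | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> ScreenResult:
    """One Mann-Whitney test per feature column; no correction by default.

    ``modality`` filters columns by prefix: "MRI" keeps T1_* columns, "PET"
    keeps PET_* columns, None keeps all feature columns. Cases with a missing
    value of a feature (excluded VOI) are dropped for that feature only.
    """
    if "label" not in table.columns:
        raise ValueError("feature table needs a 'label' column")
    labels = table["label"]
    classes = set(labels)
    if not {POSITIVE_LABEL, NEGATIVE_LABEL} <= classes:
        raise ValueError(f"both classes required, got {sorted(classes)}")
    columns = [c for c in table.columns if c != "label"]
    if modality == "MRI":
        columns = [c for c in columns if c.startswith("T1_")]
    elif modality == "PET":
        columns = [c for c in columns if c.startswith("PET_")]
    elif modality not in (None, "combined"):
        raise ValueError(f"unknown modality filter {modality!r}")

    rows = []
    for col in columns:
        values = table[col]
        ok = values.notna()
        x = values[ok & (labels == POSITIVE_LABEL)].to_numpy()
        y = values[ok & (labels == NEGATIVE_LABEL)].to_numpy()
        u, p = mann_whitney(x, y)
        rows.append((col, u, p))
    result = pd.DataFrame(rows, columns=["feature", "U", "p"]).set_index("feature")
    if correction == "bh":
        result["p_adj"] = _benjamini_hochberg(result["p"].to_numpy())
        result["selected"] = result["p_adj"] < alpha
    elif correction is None:
        result["selected"] = result["p"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return ScreenResult(
        table=result,
        alpha=alpha,
        n1=int((labels == POSITIVE_LABEL).sum()),
        n2=int((labels == NEGATIVE_LABEL).sum()),
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def top_k(result: ScreenResult, k: int = 8) -> list[str]:
    """The k most significant SELECTED features.

    Ties on p are broken by larger deviation of U from its null mean
    n1*n2/2, then by feature name. Returns all selected (with a warning) when
    fewer than k are significant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = result.table[result.table["selected"]].reset_index()
    if len(sub) < k:
        logger.warning("only %d significant features available for top-%d", len(sub), k)
    sub["dev"] = np.abs(sub["U"] - result.n1 * result.n2 / 2.0)
    sub = sub.sort_values(
        ["p", "dev", "feature"], ascending=[True, False, True], kind="mergesort"
    )
    return list(sub["feature"][:k])


def build_pool(
    mri_screen: ScreenResult | None,
    pet_screen: ScreenResult | None,
    mode: str,
    pet_top_k: int = 8,
    mri_top_k: int | None = None,
) -> CandidatePool:
    """Candidate features for one model.

    MRI pool: significant MRI features (optionally capped at the mri_top_k
    most significant). PET pool: significant PET features. Combined pool:
    (capped) significant MRI union the top-``pet_top_k`` PET features.
    """
    if mode == "MRI":
        if mri_screen is None:
            raise ValueError("MRI screen required")
        features = _mri_features(mri_screen, mri_top_k)
        provenance = "significant" if mri_top_k is None else f"top-{mri_top_k} significant"
    elif mode == "PET":
        if pet_screen is None:
            raise ValueError("PET screen required")
        features = pet_screen.selected
        provenance = "significant"
    elif mode == "combined":
        if mri_screen is None or pet_screen is None:
            raise ValueError("both screens required for the combined pool")
        mri_part = _mri_features(mri_screen, mri_top_k)
        pet_part = top_k(pet_screen, pet_top_k)
        features = mri_part + [f for f in pet_part if f not in mri_part]
        provenance = f"significant MRI + top-{pet_top_k} PET"
    else:
        raise ValueError(f"unknown pool mode {mode!r}")
    if not features:
        raise ValueError(
            f"empty {mode} candidate pool: no significant features; consider a larger alpha"
        )
    return CandidatePool(modality=mode, features=tuple(features), provenance=provenance)


def _mri_features(mri_screen: ScreenResult, cap: int | None) -> list[str]:
    if cap is None:
        return mri_screen.selected
    return top_k(mri_screen, cap)
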