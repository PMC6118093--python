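"""Cross-validated evaluation of the selected models.

Three schemes: leave-one-out, stratified 5-fold, stratified 10-fold.
Two modes:

* ``fixed_subset`` (default) — the feature subset is selected once on the full
  cohort, and only the coefficients are refit per training fold. This mirrors
  validating "the resulting model" but inherits the optimism of the selection
  step.
* ``nested`` — Mann-Whitney screening, pool construction and best-subset
  search are repeated inside every training fold; the out-of-fold predictions
  are then free of selection bias.

Metrics (accuracy, sensitivity, specificity, AUC; recurrence positive) are
computed from the pooled out-of-fold predicted probabilities at the operating
threshold (default 0.5).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import screening
from .modelling import (
    MetricsReport,
    as_binary_labels,
    best_subset,
    fit_logistic,
    metrics_from_scores,
)
from .screening import CandidatePool

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CvScheme:
    kind: str  # "loocv" | "kfold"
    k: int | None = None
    stratified: bool = True
    seed: int = 17

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and (self.k is None or self.k < 2):
            raise ValueError("k-fold CV needs k >= 2")

    @property
    def name(self) -> str:
        return "LOOCV" if self.kind == "loocv" else f"{self.k}-fold"


LOOCV = CvScheme("loocv")
FIVE_FOLD = CvScheme("kfold", 5)
TEN_FOLD = CvScheme("kfold", 10)


def make_folds(labels, scheme: CvScheme) -> list[np.ndarray]:
    """Test-index arrays partitioning the cohort; deterministic given the seed."""
    yb = as_binary_labels(labels)
    n = len(yb)
    if scheme.kind == "loocv":
        folds = [np.array([i]) for i in range(n)]
    else:
        if n < scheme.k:
            raise ValueError(f"cannot make {scheme.k} folds from {n} cases")
        cls = StratifiedKFold if scheme.stratified else KFold
        splitter = cls(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        folds = [test for _, test in splitter.split(np.zeros(n), yb)]
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        if len(np.unique(yb[train])) < 2:
            raise ValueError("a class is absent from a training split; cohort too small")
    return folds


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    scheme: CvScheme
    mode: str  # "fixed_subset" | "nested"
    predictions: pd.Series  # pooled out-of-fold probabilities, index = case_id
    labels: pd.Series
    metrics: MetricsReport
    fold_diagnostics: list[dict]
    subset: tuple[str, ...] | None  # fixed-subset mode only

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "mode": self.mode,
            **self.metrics.as_dict(),
            "subset": list(self.subset) if self.subset else None,
        }


def _screen_and_pool(table: pd.DataFrame, pool_mode: str, alpha: float,
                     pet_top_k: int, mri_top_k: int | None) -> CandidatePool:
    mri = screening.screen_features(table, "MRI", alpha=alpha) if pool_mode in ("MRI", "combined") else None
    pet = screening.screen_features(table, "PET", alpha=alpha) if pool_mode in ("PET", "combined") else None
    return screening.build_pool(mri, pet, pool_mode, pet_top_k=pet_top_k, mri_top_k=mri_top_k)


def cross_validate(
    table: pd.DataFrame,
    pool: CandidatePool | None,
    scheme: CvScheme,
    mode: str = "fixed_subset",
    max_vars: int = 5,
    threshold: float = 0.5,
    alpha: float = 0.05,
    pet_top_k: int = 8,
    mri_top_k: int | None = None,
    pool_mode: str | None = None,
) -> ValidationReport:
    """Pooled out-of-fold evaluation of one model.

    ``fixed_subset`` requires ``pool``; ``nested`` requires ``pool_mode``
    (MRI / PET / combined) so screening and selection can be redone per fold.
    Cases with missing values in the relevant columns (excluded VOIs) are
    dropped before folding.
    """
    if mode not in ("fixed_subset", "nested"):
        raise ValueError(f"unknown CV mode {mode!r}")
    if mode == "fixed_subset" and pool is None:
        raise ValueError("fixed_subset mode needs a candidate pool")
    if pool_mode is None and pool is not None:
        pool_mode = pool.modality
    if mode == "nested" and pool_mode is None:
        raise ValueError("nested mode needs pool_mode")

    if mode == "fixed_subset":
        relevant = list(pool.features)
    else:
        prefixes = {"MRI": ("T1_",), "PET": ("PET_",), "combined": ("T1_", "PET_")}[pool_mode]
        relevant = [c for c in table.columns if c.startswith(prefixes)]
    keep = table[relevant].notna().all(axis=1)
    if not keep.all():
        logger.info("%s: dropping %d cases with excluded VOIs", scheme.name, int((~keep).sum()))
    data = table[keep]
    labels = data["label"]
    yb = as_binary_labels(labels)

    folds = make_folds(labels, scheme)
    preds = np.full(len(data), np.nan)
    diagnostics: list[dict] = []

    fixed_subset: tuple[str, ...] | None = None
    if mode == "fixed_subset":
        fixed_subset = best_subset(data, pool, max_vars=max_vars).subset

    for fold_id, test in enumerate(folds):
        train = np.setdiff1d(np.arange(len(data)), test)
        train_tab = data.iloc[train]
        if mode == "fixed_subset":
            subset = fixed_subset
        else:
            try:
                fold_pool = _screen_and_pool(train_tab, pool_mode, alpha, pet_top_k, mri_top_k)
                subset = best_subset(train_tab, fold_pool, max_vars=max_vars).subset
            except ValueError as exc:
                # nothing survives screening (or every subset separates) in
                # this training fold: fall back to the intercept-only model
                logger.info("%s fold %d: %s; intercept-only fallback", scheme.name, fold_id, exc)
                subset = ()
        fit = fit_logistic(train_tab[list(subset)], yb[train])
        preds[test] = fit.predict_proba(data.iloc[test][list(subset)])
        diagnostics.append(
            {"fold": fold_id, "n_test": len(test), "subset": list(subset),
             "separated": fit.separated, "converged": fit.converged}
        )
        if fit.separated:
            logger.info("%s fold %d: separation; using last iterate", scheme.name, fold_id)

    assert not np.isnan(preds).any()
    return ValidationReport(
        scheme=scheme,
        mode=mode,
        predictions=pd.Series(preds, index=data.index, name="p_recurrence"),
        labels=labels,
        metrics=metrics_from_scores(preds, yb, threshold=threshold),
        fold_diagnostics=diagnostics,
        subset=fixed_subset,
    )


def apparent_performance(
    table: pd.DataFrame, pool: CandidatePool, max_vars: int = 5, threshold: float = 0.5
):
    """Resubstitution fit and metrics on the full cohort (no cross-validation)."""
    keep = table[list(pool.features)].notna().all(axis=1)
    data = table[keep]
    yb = as_binary_labels(data["label"])
    result = best_subset(data, pool, max_vars=max_vars)
    scores = result.predict_proba(data)
    return result, metrics_from_scores(scores, yb, threshold=threshold)


def report(runs: dict[str, dict[str, ValidationReport | MetricsReport]]) -> pd.DataFrame:
    """Flatten {modality: {scheme_name: report}} into a tidy metric table."""
    rows = []
    for modality, by_scheme in runs.items():
        for scheme_name, rep in by_scheme.items():
            metrics = rep.metrics if isinstance(rep, ValidationReport) else rep
            rows.append(
                {"modality": modality, "scheme": scheme_name,
                 "accuracy": metrics.accuracy, "sensitivity": metrics.sensitivity,
                 "specificity": metrics.specificity, "auc": metrics.auc}
            )
    return pd.DataFrame(rows)
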