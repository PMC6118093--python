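"""Logistic regression, exhaustive best-subset AIC search, and metrics.

The classifier is an ordinary maximum-likelihood logistic regression of the
binary outcome (positive class = recurrence) on a small feature subset. The
subset is found by exhaustively fitting every subset of the candidate pool up
to ``max_vars`` (default 5) predictors and keeping the fit with the lowest
AIC = 2k - 2 logL (k counts the intercept). Ties go to fewer variables, then
to lexicographic feature order. Subsets that fail to converge or show
quasi-complete separation are excluded from the ranking.

Predictors are z-scored internally for numerical stability; AIC is invariant
to that affine rescaling, and coefficients are reported on both scales.

The model/results split follows the statsmodels convention:
``BestSubsetLogit(table, pool).fit()`` returns a
:class:`BestSubsetLogitResults` carrying the winning subset, coefficients,
log-likelihood, AIC and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "recurrence"

_MAX_ETA = 30.0
_SEPARATION_COEF = 15.0
_CONV_TOL = 1e-10
_MAX_ITER = 50


def as_binary_labels(y) -> np.ndarray:
    """Map labels to {0, 1} with recurrence = 1."""
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        return (arr == POSITIVE_LABEL).astype(float)
    return arr.astype(float)


def _batched_irls(
    designs: np.ndarray, y: np.ndarray, tol: float = _CONV_TOL, max_iter: int = _MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS over a stack of design matrices.

    designs: (C, n, k) including the intercept column. Returns
    (beta (C,k), llf (C,), converged (C,), separated (C,)).
    """
    C, n, k = designs.shape
    beta = np.zeros((C, k))
    llf = np.full(C, -np.inf)
    converged = np.zeros(C, dtype=bool)
    separated = np.zeros(C, dtype=bool)
    eye = np.eye(k)
    alive = np.arange(C)
    Xa = designs
    ba = np.zeros((C, k))
    llf_prev = np.full(C, -np.inf)
    for _ in range(max_iter):
        eta = np.clip((Xa @ ba[:, :, None])[:, :, 0], -_MAX_ETA, _MAX_ETA)
        mu = 1.0 / (1.0 + np.exp(-eta))
        llf_a = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
        llf[alive] = llf_a
        beta[alive] = ba
        done = np.abs(llf_a - llf_prev) < tol
        converged[alive[done]] = True
        if done.all():
            break
        keep = ~done
        alive = alive[keep]
        Xa, ba, mu, eta = Xa[keep], ba[keep], mu[keep], eta[keep]
        llf_prev = llf_a[keep]
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = (Xa.transpose(0, 2, 1) @ (y - mu)[:, :, None])[:, :, 0]
        hess = Xa.transpose(0, 2, 1) @ (Xa * w[:, :, None])
        ba_new = ba + np.linalg.solve(hess + 1e-10 * eye, grad[:, :, None])[:, :, 0]
        # Quasi-complete separation drives the standardised coefficients to
        # extremes (and a capped linear predictor can make the deviance
        # plateau and look "converged"), so runaway subsets are flagged and
        # retired early, keeping their last stable iterate.
        blown = np.abs(ba_new).max(axis=1) > _SEPARATION_COEF
        if blown.any():
            separated[alive[blown]] = True
            ok = ~blown
            alive, Xa, llf_prev = alive[ok], Xa[ok], llf_prev[ok]
            ba = ba_new[ok]
            if len(alive) == 0:
                break
        else:
            ba = ba_new
    separated |= np.abs(beta).max(axis=1) > _SEPARATION_COEF
    return beta, llf, converged, separated


@dataclasses.dataclass(frozen=True)
class LogisticFit:
    """One maximum-likelihood logistic fit on a fixed feature subset."""

    features: tuple[str, ...]
    params: pd.Series  # raw-scale coefficients, index = ['intercept', *features]
    params_standardized: pd.Series  # on z-scored predictors
    llf: float
    converged: bool
    separated: bool
    n_obs: int

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.features) - set(X.columns)
            if missing:
                raise ValueError(f"missing predictors: {sorted(missing)}")
            X = X[list(self.features)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        eta = self.params.iloc[0] + X @ self.params.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -_MAX_ETA, _MAX_ETA)))


def _standardize(X: np.ndarray, names) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    bad = [n for n, s in zip(names, sd) if s == 0]
    if bad:
        raise ValueError(f"constant predictors: {bad}")
    return (X - mean) / sd, mean, sd


def _raw_params(beta_std: np.ndarray, mean: np.ndarray, sd: np.ndarray, names) -> pd.Series:
    slopes = beta_std[1:] / sd
    intercept = beta_std[0] - float(slopes @ mean)
    return pd.Series([intercept, *slopes], index=["intercept", *names])


def fit_logistic(X, y, feature_names=None) -> LogisticFit:
    """MLE logistic regression (Newton/IRLS on z-scored predictors)."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    yb = as_binary_labels(y)
    classes = np.unique(yb)
    if len(classes) < 2 and X.shape[1] > 0:
        raise ValueError("both classes must be present")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("too few observations for the number of predictors")
    if X.shape[1] == 0:
        design = np.ones((len(yb), 1))
        mean = sd = np.empty(0)
        Z = X
    else:
        Z, mean, sd = _standardize(X, feature_names)
        design = np.column_stack([np.ones(len(yb)), Z])
    beta, llf, converged, separated = _batched_irls(design[None], yb)
    beta_std = beta[0]
    params_std = pd.Series(beta_std, index=["intercept", *feature_names])
    params_raw = (
        _raw_params(beta_std, mean, sd, feature_names)
        if X.shape[1]
        else params_std.copy()
    )
    if separated[0]:
        logger.info("quasi-complete separation detected for %s", feature_names)
    return LogisticFit(
        features=tuple(feature_names),
        params=params_raw,
        params_standardized=params_std,
        llf=float(llf[0]),
        converged=bool(converged[0]),
        separated=bool(separated[0]),
        n_obs=len(yb),
    )


class BestSubsetLogit:
    """Exhaustive best-subset logistic model on a candidate feature pool.

    Parameters
    ----------
    table : DataFrame with the candidate feature columns and a ``label``
        column (or pass ``y`` explicitly).
    pool : iterable of candidate feature names (or a screening CandidatePool).
    max_vars : subset size cap (default 5).
    """

    def __init__(self, table: pd.DataFrame, pool, y=None, max_vars: int = 5, chunk: int = 20000):
        features = tuple(getattr(pool, "features", pool))
        if not features:
            raise ValueError("empty candidate pool")
        if y is None:
            if "label" not in table.columns:
                raise ValueError("no 'label' column and no y given")
            y = table["label"]
        data = table[list(features)]
        keep = data.notna().all(axis=1)
        if not keep.all():
            logger.info("dropping %d cases with missing pool features", int((~keep).sum()))
        self.table = data[keep]
        self.y = as_binary_labels(np.asarray(y)[np.asarray(keep)])
        self.pool = tuple(sorted(features))
        self.max_vars = int(max_vars)
        self.chunk = int(chunk)
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    def fit(self) -> "BestSubsetLogitResults":
        X = self.table[list(self.pool)].to_numpy(dtype=float)
        Z, mean, sd = _standardize(X, self.pool)
        n = len(self.y)
        best: tuple[float, tuple[int, ...], np.ndarray, float] | None = None
        n_fitted = n_excluded = 0
        for size in range(1, min(self.max_vars, len(self.pool)) + 1):
            combos = np.array(list(itertools.combinations(range(len(self.pool)), size)), dtype=int)
            for start in range(0, len(combos), self.chunk):
                batch = combos[start : start + self.chunk]
                designs = np.empty((len(batch), n, size + 1))
                designs[:, :, 0] = 1.0
                designs[:, :, 1:] = Z[:, batch].transpose(1, 0, 2)
                beta, llf, converged, separated = _batched_irls(designs, self.y)
                valid = converged & ~separated
                n_fitted += len(batch)
                n_excluded += int((~valid).sum())
                aic = 2.0 * (size + 1) - 2.0 * llf
                for idx in np.nonzero(valid)[0]:
                    # Sizes ascend and combos are lexicographic, so on an exact
                    # tie the earlier (smaller, lexicographically first) wins.
                    if best is None or aic[idx] < best[0] - 1e-9:
                        best = (float(aic[idx]), tuple(batch[idx]), beta[idx].copy(), float(llf[idx]))
        if best is None:
            raise ValueError("every candidate subset was separated or failed to converge")
        if n_excluded:
            logger.info("best-subset search: %d/%d subsets excluded", n_excluded, n_fitted)
        _, subset_idx, beta_std, llf = best
        names = [self.pool[i] for i in subset_idx]
        params_std = pd.Series(beta_std, index=["intercept", *names])
        params_raw = _raw_params(beta_std, mean[list(subset_idx)], sd[list(subset_idx)], names)
        fit = LogisticFit(
            features=tuple(names),
            params=params_raw,
            params_standardized=params_std,
            llf=llf,
            converged=True,
            separated=False,
            n_obs=n,
        )
        return BestSubsetLogitResults(self, fit, n_fitted, n_excluded)


@dataclasses.dataclass(frozen=True)
class BestSubsetLogitResults:
    """Winning subset and its maximum-likelihood fit."""

    model: BestSubsetLogit
    fit: LogisticFit
    n_subsets_fitted: int
    n_subsets_excluded: int

    @property
    def subset(self) -> tuple[str, ...]:
        return self.fit.features

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def llf(self) -> float:
        return self.fit.llf

    @property
    def aic(self) -> float:
        return self.fit.aic

    def predict_proba(self, X) -> np.ndarray:
        return self.fit.predict_proba(X)

    def summary(self) -> str:
        lines = [
            "Best-subset logistic regression (AIC)",
            "=" * 54,
            f"n obs:            {self.fit.n_obs}",
            f"pool size:        {len(self.model.pool)}",
            f"max subset size:  {self.model.max_vars}",
            f"subsets fitted:   {self.n_subsets_fitted} ({self.n_subsets_excluded} excluded)",
            f"log-likelihood:   {self.fit.llf:.6f}",
            f"AIC:              {self.fit.aic:.6f}",
            "-" * 54,
            f"{'term':<30}{'coef (raw)':>12}{'coef (z)':>12}",
        ]
        for name in self.fit.params.index:
            lines.append(
                f"{name:<30}{self.fit.params[name]:>12.5f}"
                f"{self.fit.params_standardized[name]:>12.5f}"
            )
        return "\n".join(lines)


def best_subset(table: pd.DataFrame, pool, max_vars: int = 5, y=None) -> BestSubsetLogitResults:
    """Functional wrapper around :class:`BestSubsetLogit`."""
    return BestSubsetLogit(table, pool, y=y, max_vars=max_vars).fit()


# ---------------------------------------------------------------------------
# Metrics

@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and rates at an operating threshold, plus AUC."""

    tp: int
    fn: int
    tn: int
    fp: int
    auc: float
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "threshold": self.threshold,
        }


def auc(scores, y) -> float:
    """AUC from the rank (Mann-Whitney) statistic with mid-rank tie handling."""
    scores = np.asarray(scores, dtype=float)
    yb = as_binary_labels(y).astype(bool)
    n1 = int(yb.sum())
    n0 = int((~yb).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[yb].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classify(fit: LogisticFit, X, y, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts and rates; recurrence is the positive class."""
    proba = fit.predict_proba(X)
    yb = as_binary_labels(y).astype(bool)
    pred = proba >= threshold
    return MetricsReport(
        tp=int((pred & yb).sum()),
        fn=int((~pred & yb).sum()),
        tn=int((~pred & ~yb).sum()),
        fp=int((pred & ~yb).sum()),
        auc=auc(proba, yb),
        threshold=threshold,
    )


def metrics_from_scores(scores, y, threshold: float = 0.5) -> MetricsReport:
    """Metrics from precomputed probabilities (used for pooled CV predictions)."""
    scores = np.asarray(scores, dtype=float)
    yb = as_binary_labels(y).astype(bool)
    pred = scores >= threshold
    return MetricsReport(
        tp=int((pred & yb).sum()),
        fn=int((~pred & yb).sum()),
        tn=int((~pred & ~yb).sum()),
        fp=int((pred & ~yb).sum()),
        auc=auc(scores, yb),
        threshold=threshold,
    )


def youden_threshold(scores, y) -> float:
    """Operating point maximising sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    yb = as_binary_labels(y).astype(bool)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & yb).sum() / max(yb.sum(), 1)
        spec = (~pred & ~yb).sum() / max((~yb).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t
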