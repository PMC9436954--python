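"""Supervised signal classifiers: random forest and gradient boosting.

Pipeline, mirroring standard practice for label-based signal detection:

1. the gold standard (label-positive Y and label-negative N pairs) is
   split 75/25 with stratification;
2. class imbalance is corrected with SMOTE — synthetic minority rows are
   convex combinations of a minority row and one of its k nearest minority
   neighbors.  Balancing happens strictly on training data: after the
   split, and inside each cross-validation training fold during tuning,
   so no synthetic copy ever leaks into evaluation data;
3. hyperparameters are tuned by fivefold stratified cross-validation,
   maximizing the mean balanced AUROC (sensitivity + specificity)/2 at
   the per-fold optimal threshold, then the winner is refit on the full
   (balanced) training set;
4. the signaling threshold is the probability maximizing the balanced
   AUROC over out-of-fold training scores (exhaustive scan over observed
   score values plus the 0/1 sentinels; flag rule is score >= threshold;
   ties break to the smallest maximizing threshold).  Out-of-fold rather
   than resubstitution scores keep the threshold at a generalizable
   operating point.

All stochastic steps take explicit seeds and are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger("pvsignal")

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "GoldStandardSplit",
    "TrainedSignalModel",
    "split_gold_standard",
    "smote_balance",
    "select_threshold",
    "balanced_auroc_at_best_threshold",
    "tune_and_fit",
    "score_pairs",
]

ALGORITHMS = ("gbm", "rf")

#: Small documented grids: tree count and depth for both ensembles,
#: learning rate fixed for GBM, feature subsampling varied for RF.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "rf": [
        {"n_estimators": 100, "max_depth": 3, "max_features": "sqrt"},
        {"n_estimators": 100, "max_depth": None, "max_features": "sqrt"},
    ],
    "gbm": [
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 2},
        {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    ],
}


@dataclass(frozen=True)
class GoldStandardSplit:
    """Stratified train/test partition of the Y/N gold standard."""

    train_pairs: tuple[str, ...]
    test_pairs: tuple[str, ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_pairs) & set(self.test_pairs)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class TrainedSignalModel:
    """A fitted classifier plus its tuned configuration and threshold."""

    algorithm: str
    estimator: object
    feature_columns: tuple[str, ...]
    tuned_hyperparameters: dict
    threshold: float
    cv_summary: list[dict] = field(default_factory=list)
    seed: int = 0


def _as_labels(labels: Sequence) -> np.ndarray:
    """Accept Y/N strings or booleans; return a boolean array (True = Y)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        bad = set(np.unique(arr)) - {"Y", "N"}
        if bad:
            raise ValueError(f"labels must be Y/N, got {sorted(bad)}")
        return arr == "Y"
    return arr.astype(bool)


def split_gold_standard(
    features: pd.DataFrame,
    labels: Sequence,
    fraction: float = 0.75,
    seed: int = 0,
) -> GoldStandardSplit:
    """Stratified random split of labeled pairs into train and test sets.

    Both classes must have at least two members so each side of the split
    sees both labels.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = _as_labels(labels)
    if len(y) != len(features):
        raise ValueError("labels and features must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError(
            f"cannot stratify: class counts Y={n_pos}, N={n_neg} (need >= 2 each)"
        )
    idx_train, idx_test = train_test_split(
        np.arange(len(y)),
        train_size=fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )
    pairs = np.asarray(features.index, dtype=object)
    return GoldStandardSplit(
        train_pairs=tuple(sorted(pairs[idx_train])),
        test_pairs=tuple(sorted(pairs[idx_test])),
        train_fraction=fraction,
        seed=seed,
    )


def smote_balance(
    features: pd.DataFrame,
    labels: Sequence,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic minority oversampling to equal class counts.

    Original rows are preserved verbatim; each synthetic row is
    ``x_i + lam * (x_j - x_i)`` with ``lam ~ U(0,1)``, ``x_i`` a random
    minority row and ``x_j`` one of its ``k_neighbors`` nearest minority
    neighbors (Euclidean).  Synthetic rows get index labels
    ``"<pair>__smote<i>"``.  Requires minority count >= k_neighbors + 1.
    """
    y = _as_labels(labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == n_neg:
        return features.copy(), y.copy()
    minority_flag = n_pos < n_neg
    minority = features.loc[y == minority_flag]
    n_needed = abs(n_pos - n_neg)
    if len(minority) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(minority)} member(s); SMOTE with "
            f"k_neighbors={k_neighbors} needs at least {k_neighbors + 1} — "
            "reduce k_neighbors"
        )
    rng = np.random.default_rng(seed)
    X_min = minority.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, neighbor_idx = nn.kneighbors(X_min)  # column 0 is the row itself
    base_rows = rng.integers(0, len(X_min), size=n_needed)
    pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    lam = rng.random(n_needed)
    partners = neighbor_idx[base_rows, pick]
    synthetic = X_min[base_rows] + lam[:, None] * (X_min[partners] - X_min[base_rows])
    synth_index = [
        f"{minority.index[base_rows[i]]}__smote{i}" for i in range(n_needed)
    ]
    synth_frame = pd.DataFrame(synthetic, index=synth_index,
                               columns=features.columns)
    out_X = pd.concat([features, synth_frame])
    out_y = np.concatenate([y, np.full(n_needed, minority_flag)])
    return out_X, out_y


def _threshold_metrics(
    scores: np.ndarray, y: np.ndarray, threshold: float
) -> tuple[float, float]:
    flags = scores >= threshold
    pos = y
    sens = float((flags & pos).sum() / pos.sum())
    spec = float((~flags & ~pos).sum() / (~pos).sum())
    return sens, spec


def select_threshold(scores: Sequence[float], labels: Sequence) -> float:
    """AUROC-optimal probability threshold.

    Scans the distinct score values plus the 0 and 1 sentinels; the flag
    rule is ``score >= threshold``; returns the smallest threshold
    maximizing (sensitivity + specificity)/2.
    """
    y = _as_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must align")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to select a threshold")
    candidates = np.unique(np.concatenate([s, [0.0, 1.0]]))
    best_t, best_value = None, -np.inf
    for t in candidates:  # ascending, so ties keep the smallest maximizer
        sens, spec = _threshold_metrics(s, y, t)
        value = (sens + spec) / 2.0
        if value > best_value + 1e-12:
            best_value, best_t = value, float(t)
    return best_t


def balanced_auroc_at_best_threshold(
    scores: Sequence[float], labels: Sequence
) -> float:
    """Max over thresholds of (sensitivity + specificity)/2."""
    y = _as_labels(labels)
    s = np.asarray(scores, dtype=float)
    t = select_threshold(s, y)
    sens, spec = _threshold_metrics(s, y, t)
    return (sens + spec) / 2.0


def _make_estimator(algorithm: str, params: Mapping, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if algorithm == "gbm":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}; use one of {ALGORITHMS}")


def _fit_balanced(algorithm, params, X, y, k_neighbors, seed):
    """SMOTE-balance (when feasible) then fit one estimator."""
    minority = int(min(y.sum(), (~y).sum()))
    if minority >= 2 and y.sum() != (~y).sum():
        k = min(k_neighbors, minority - 1)
        Xb, yb = smote_balance(X, y, k_neighbors=k, seed=seed)
    else:
        if minority < 2 and y.sum() != (~y).sum():
            logger.warning(
                "tune_and_fit: minority class of %d row(s); fitting unbalanced",
                minority,
            )
        Xb, yb = X, y
    est = _make_estimator(algorithm, params, seed)
    est.fit(Xb.to_numpy(dtype=float), yb)
    return est


def tune_and_fit(
    algorithm: str,
    features: pd.DataFrame,
    labels: Sequence,
    folds: int = 5,
    grid: Sequence[Mapping] | None = None,
    seed: int = 0,
    k_neighbors: int = 5,
) -> TrainedSignalModel:
    """Grid search by stratified CV, refit on the full training set.

    Candidate configurations are ranked by mean cross-validated balanced
    AUROC at the per-fold optimal threshold; SMOTE runs inside each
    training fold.  The returned model carries the refit estimator, the
    winning hyperparameters, the per-fold CV summary and the threshold
    selected on the winner's out-of-fold training scores.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = list(grid if grid is not None else DEFAULT_GRIDS[algorithm])
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    y = _as_labels(labels)
    minority = int(min(y.sum(), (~y).sum()))
    if minority < 2:
        raise ValueError(
            f"cannot run stratified CV with a class of {minority} member(s)"
        )
    n_splits = min(folds, minority)
    if n_splits < folds:
        logger.info(
            "tune_and_fit(%s): reducing folds %d -> %d (minority class size)",
            algorithm, folds, n_splits,
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    X_arr = features

    results = []
    for params in grid:
        fold_scores = []
        for train_idx, val_idx in skf.split(X_arr, y):
            X_tr, y_tr = X_arr.iloc[train_idx], y[train_idx]
            X_val, y_val = X_arr.iloc[val_idx], y[val_idx]
            if y_val.all() or (~y_val).all():
                continue  # degenerate fold: no threshold metric defined
            est = _fit_balanced(algorithm, params, X_tr, y_tr, k_neighbors, seed)
            val_scores = est.predict_proba(X_val.to_numpy(dtype=float))[:, 1]
            fold_scores.append(balanced_auroc_at_best_threshold(val_scores, y_val))
        if not fold_scores:
            raise ValueError("every CV fold was single-class; cannot tune")
        results.append(
            {
                "params": dict(params),
                "mean_cv_auroc": float(np.mean(fold_scores)),
                "fold_aurocs": [float(v) for v in fold_scores],
            }
        )

    best = max(range(len(results)), key=lambda i: results[i]["mean_cv_auroc"])
    winner = results[best]["params"]
    estimator = _fit_balanced(algorithm, winner, X_arr, y, k_neighbors, seed)
    # Threshold from out-of-fold training scores: tree ensembles memorize
    # small training sets, so resubstitution scores are near-separable and
    # would push the threshold to the extreme of the score range.
    oof_scores = np.full(len(y), np.nan)
    for train_idx, val_idx in skf.split(X_arr, y):
        fold_est = _fit_balanced(
            algorithm, winner, X_arr.iloc[train_idx], y[train_idx],
            k_neighbors, seed,
        )
        oof_scores[val_idx] = fold_est.predict_proba(
            X_arr.iloc[val_idx].to_numpy(dtype=float)
        )[:, 1]
    threshold = select_threshold(oof_scores, y)
    return TrainedSignalModel(
        algorithm=algorithm,
        estimator=estimator,
        feature_columns=tuple(features.columns),
        tuned_hyperparameters=dict(winner),
        threshold=threshold,
        cv_summary=results,
        seed=seed,
    )


def score_pairs(model: TrainedSignalModel, features: pd.DataFrame) -> pd.Series:
    """Signaling probabilities for each pair (row) in ``features``.

    The feature schema must match the training schema exactly; missing or
    extra columns raise with both lists named.
    """
    missing = [c for c in model.feature_columns if c not in features.columns]
    extra = [c for c in features.columns if c not in model.feature_columns]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, extra={extra}"
        )
    ordered = features.loc[:, list(model.feature_columns)]
    probs = model.estimator.predict_proba(ordered.to_numpy(dtype=float))[:, 1]
    return pd.Series(probs, index=features.index, name=f"{model.algorithm}_prob")
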