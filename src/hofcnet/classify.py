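"""Edge-feature classification with nested leave-one-out cross-validation.

Features are the strict upper-triangle edge weights of a (refined) network.
Feature selection is a two-sample t-test inside every training fold; the
classifier is a linear soft-margin SVM.  An inner LOOCV restricted to the
training subjects picks the estimator hyperparameter from a grid; the outer
LOOCV aggregates per-fold confusion counts into accuracy / sensitivity /
specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .errors import HofcnetError, UndefinedMetricError
from .types import check_symmetric

__all__ = [
    "FeatureVector",
    "EvalResult",
    "vectorize_upper_triangle",
    "ttest_select",
    "train_linear_svm",
    "compute_metrics",
    "inner_select_param",
    "nested_loocv",
]

#: a recipe maps (per-subject data, hyperparameter value) -> network matrix
Recipe = Callable[[Any, Any], np.ndarray]


@dataclass
class FeatureVector:
    """Upper-triangle edge weights of one subject's network."""

    values: np.ndarray
    subject_id: str = ""
    label: int = 0


@dataclass
class EvalResult:
    """Aggregated confusion counts and derived metrics.

    ``fold_params`` records the hyperparameter chosen for each outer fold (in
    cohort order) and ``fold_feature_idx`` the indices of the features that
    the training-side t-test selected in that fold.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    fold_params: list = field(default_factory=list)
    fold_feature_idx: list = field(default_factory=list)
    predictions: list = field(default_factory=list)


def vectorize_upper_triangle(w: np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order; length P(P-1)/2."""
    w = check_symmetric(w)
    iu = np.triu_indices(w.shape[0], k=1)
    return np.asarray(w[iu], dtype=float)


def ttest_select(
    features: np.ndarray,
    labels: np.ndarray,
    p_thresh: float,
    *,
    welch: bool = False,
) -> np.ndarray:
    """Boolean mask of features whose two-sample t-test p-value is < p_thresh.

    Uses the pooled-variance (classic) two-sided test by default; set
    ``welch=True`` for the unequal-variance variant.  Features that are
    constant across all subjects get an undefined statistic and are excluded.
    If no feature passes, the single smallest-p feature is selected so the
    downstream classifier always has input.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    pos = features[labels > 0]
    neg = features[labels < 0]
    if len(pos) < 2 or len(neg) < 2:
        raise HofcnetError(
            f"t-test needs >= 2 subjects per class, got {len(pos)} / {len(neg)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(pos, neg, axis=0, equal_var=not welch)
    pvals = np.asarray(pvals, dtype=float)
    mask = pvals < p_thresh
    if not mask.any():
        finite = np.where(np.isfinite(pvals), pvals, np.inf)
        if np.all(np.isinf(finite)):
            # every feature constant: fall back to the first one
            mask[0] = True
        else:
            mask[int(np.argmin(finite))] = True
    return mask


def train_linear_svm(features: np.ndarray, labels: np.ndarray, c: float = 1.0) -> SVC:
    """Fit a linear soft-margin SVM (hinge loss, penalty C)."""
    if c <= 0:
        raise ValueError(f"C must be positive, got {c}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise HofcnetError("SVM training requires both classes present")
    clf = SVC(kernel="linear", C=c, tol=1e-6)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalResult:
    """Accuracy, sensitivity and specificity from confusion counts."""
    for name, v in (("TP", tp), ("TN", tn), ("FP", fp), ("FN", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if tp + fn == 0:
        raise UndefinedMetricError("no positive subjects: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetricError("no negative subjects: specificity undefined")
    total = tp + tn + fp + fn
    return EvalResult(
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        acc=(tp + tn) / total,
        sen=tp / (tp + fn),
        spe=tn / (tn + fp),
    )


def _fold_scaler(train_features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and (floored) standard deviation of a training fold."""
    mu = train_features.mean(axis=0)
    sd = train_features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _loo_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    p_thresh: float,
    c: float,
    scale: bool,
) -> float:
    """Leave-one-out accuracy with selection and training redone per fold.

    When ``scale`` is set, features are z-scored with statistics fitted on
    the fold's training side only (no leakage).  Folds whose training side
    loses a whole class (possible only in tiny cohorts) are skipped rather
    than counted.
    """
    n = len(labels)
    hits, counted = 0, 0
    for v in range(n):
        tr = np.concatenate([np.arange(v), np.arange(v + 1, n)])
        y_tr = labels[tr]
        if (y_tr > 0).sum() < 2 or (y_tr < 0).sum() < 2:
            continue
        mask = ttest_select(features[tr], y_tr, p_thresh)
        f_tr = features[tr][:, mask]
        f_te = features[v : v + 1, mask]
        if scale:
            mu, sd = _fold_scaler(f_tr)
            f_tr = (f_tr - mu) / sd
            f_te = (f_te - mu) / sd
        clf = train_linear_svm(f_tr, y_tr, c)
        pred = clf.predict(f_te)[0]
        hits += int(pred == labels[v])
        counted += 1
    if counted == 0:
        raise HofcnetError("no feasible inner folds: cohort too small")
    return hits / counted


def inner_select_param(
    features_by_value: Sequence[np.ndarray],
    labels: np.ndarray,
    grid: Sequence,
    *,
    p_thresh: float = 0.05,
    c: float = 1.0,
    scale_features: bool = True,
) -> tuple[Any, int]:
    """Pick the grid value maximizing inner-LOOCV accuracy over the training set.

    ``features_by_value[g]`` holds the training subjects' feature matrix for
    grid value ``grid[g]``.  Ties are broken in favour of the earliest grid
    entry.  Returns ``(value, index)``.
    """
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be non-empty")
    if len(features_by_value) != len(grid):
        raise ValueError("one feature matrix per grid value is required")
    best_idx, best_acc = 0, -1.0
    for g, feats in enumerate(features_by_value):
        acc = _loo_accuracy(
            np.asarray(feats, dtype=float), labels, p_thresh, c, scale_features
        )
        if acc > best_acc:
            best_idx, best_acc = g, acc
    return grid[best_idx], best_idx


def nested_loocv(
    cohort: Sequence[tuple[str, Any, int]],
    recipe: Recipe,
    grid: Sequence,
    *,
    p_thresh: float = 0.05,
    c: float = 1.0,
    scale_features: bool = True,
) -> EvalResult:
    """Outer LOOCV with inner hyperparameter selection on the training folds.

    Parameters
    ----------
    cohort
        ``(subject_id, data, label)`` triples with labels in {+1, -1}; the
        positive class is the patient group.
    recipe
        Deterministic map from one subject's data and a grid value to a
        symmetric network; evaluated per subject, independent of every other
        subject, so it can safely be precomputed outside the folds.
    grid
        Ordered hyperparameter values (regularizer strengths or keep-fractions).
    scale_features
        Z-score the selected features with statistics fitted on the training
        side of each fold.  With the SVM penalty fixed this makes the
        classifier invariant to the overall magnitude of the edge weights,
        which varies over orders of magnitude across estimators.

    Returns
    -------
    EvalResult
        Confusion counts aggregated over all outer folds, per-fold chosen
        hyperparameters, selected-feature indices, and predictions.
    """
    n = len(cohort)
    if n < 4:
        raise HofcnetError(f"nested LOOCV needs at least 4 subjects, got {n}")
    labels = np.asarray([lab for _, _, lab in cohort])
    if not ((labels > 0).any() and (labels < 0).any()):
        raise HofcnetError("both classes must be present in the cohort")
    if len(grid) == 0:
        raise ValueError("hyperparameter grid must be non-empty")

    # per-subject feature matrices for every grid value (unsupervised, no leakage)
    features_by_value = []
    for g in grid:
        rows = []
        for sid, data, _ in cohort:
            try:
                rows.append(vectorize_upper_triangle(recipe(data, g)))
            except Exception as err:
                raise HofcnetError(
                    f"estimator failed for subject {sid!r} at grid value {g!r}: {err}"
                ) from err
        features_by_value.append(np.vstack(rows))

    tp = tn = fp = fn = 0
    fold_params: list = []
    fold_feature_idx: list = []
    predictions: list = []
    for t in range(n):
        tr = np.concatenate([np.arange(t), np.arange(t + 1, n)])
        y_tr = labels[tr]
        chosen, idx = inner_select_param(
            [f[tr] for f in features_by_value], y_tr, grid,
            p_thresh=p_thresh, c=c, scale_features=scale_features,
        )
        feats = features_by_value[idx]
        try:
            mask = ttest_select(feats[tr], y_tr, p_thresh)
            f_tr = feats[tr][:, mask]
            f_te = feats[t : t + 1, mask]
            if scale_features:
                mu, sd = _fold_scaler(f_tr)
                f_tr = (f_tr - mu) / sd
                f_te = (f_te - mu) / sd
            clf = train_linear_svm(f_tr, y_tr, c)
        except HofcnetError as err:
            raise HofcnetError(f"outer fold {t + 1}: {err}") from err
        pred = int(clf.predict(f_te)[0])
        truth = int(labels[t])
        if truth > 0:
            tp += int(pred > 0)
            fn += int(pred <= 0)
        else:
            tn += int(pred <= 0)
            fp += int(pred > 0)
        fold_params.append(chosen)
        fold_feature_idx.append(np.flatnonzero(mask))
        predictions.append((cohort[t][0], truth, pred))

    result = compute_metrics(tp, tn, fp, fn)
    result.fold_params = fold_params
    result.fold_feature_idx = fold_feature_idx
    result.predictions = predictions
    return result
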