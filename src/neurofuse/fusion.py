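"""Stage 2: ranked-prefix selection and random-forest fusion.

The features of each modality, sorted by their stage-1 local KNN accuracy,
are scanned incrementally: prefixes of length 1, 2, … are each evaluated
with a random forest under stratified 4-fold cross-validation (grid search
over the number of trees and maximum depth on each training split), and
the shortest prefix attaining the maximal accuracy is kept.  The two
optimal prefixes are then concatenated into one global feature vector and
classified the same way, which is the fused diagnosis.

Sensitivity is TP/(TP+FN) with ASD the positive class; AUC is the
trapezoidal ROC area of the pooled out-of-fold autism probabilities.

A classifier comparison (random forest vs. SVM vs. naive Bayes vs. a small
feed-forward network) on the fused features is provided for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .local_classification import _as_binary_labels

__all__ = [
    "DEFAULT_GRID",
    "FAST_GRID",
    "ClassificationMetrics",
    "evaluate_feature_prefix",
    "PrefixScanCurve",
    "incremental_selection",
    "FusionModel",
    "fuse_modalities",
    "concatenate_prefixes",
    "benchmark_classifiers",
]

#: Grid-search space for the random forest: number of estimators and
#: maximum tree depth (None = unbounded).  Gini impurity throughout.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [10, 50, 100, 200],
    "max_depth": [2, 4, 8, None],
}

#: Single-point grid for simulations where the inner search is not the
#: object of study.
FAST_GRID: dict[str, list] = {"n_estimators": [100], "max_depth": [None]}

DEFAULT_FOLDS = 4
INNER_FOLDS = 3


@dataclass
class ClassificationMetrics:
    """Pooled out-of-fold metrics of one cross-validated classifier."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: tuple[int, int, int, int]  # TP, FN, TN, FP
    probabilities: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _grid_size(grid: Mapping[str, Sequence]) -> int:
    n = 1
    for v in grid.values():
        n *= len(v)
    return n


def _metrics_from_oof(y: np.ndarray, prob: np.ndarray) -> ClassificationMetrics:
    pred = prob > 0.5  # 0.5 resolves to TD
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    n = tp + fn + tn + fp
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(y, prob)) if len(np.unique(y)) == 2 else float("nan")
    return ClassificationMetrics(
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        confusion=(tp, fn, tn, fp),
        probabilities=prob,
        predictions=pred.astype(int),
    )


def _cross_validated_probabilities(
    estimator_factory,
    x: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
    score_fn=None,
) -> np.ndarray:
    """Pooled out-of-fold positive-class scores under stratified CV."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.empty(y.size)
    for fold_no, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold_no} training split contains a single class")
        est = estimator_factory()
        est.fit(x[tr], y[tr])
        if score_fn is not None:
            prob[te] = score_fn(est, x[te])
        else:
            prob[te] = est.predict_proba(x[te])[:, 1]
    return prob


def evaluate_feature_prefix(
    features: np.ndarray,
    labels,
    *,
    folds: int = DEFAULT_FOLDS,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    inner_folds: int = INNER_FOLDS,
) -> ClassificationMetrics:
    """Cross-validated random-forest metrics for a feature subset.

    Outer stratified ``folds``-fold CV; on each training split the forest's
    ``n_estimators`` and ``max_depth`` are chosen by an inner
    ``inner_folds``-fold grid search (skipped when the grid has a single
    point).  Metrics are pooled over the out-of-fold predictions.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] == 0:
        raise ValueError("empty feature set")
    y = _as_binary_labels(labels)
    grid = dict(grid if grid is not None else DEFAULT_GRID)

    def factory():
        base = RandomForestClassifier(
            criterion="gini", random_state=seed, n_jobs=1
        )
        if _grid_size(grid) == 1:
            return base.set_params(**{k: v[0] for k, v in grid.items()})
        return GridSearchCV(
            base,
            param_grid=grid,
            cv=StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed),
            scoring="accuracy",
            n_jobs=1,
        )

    prob = _cross_validated_probabilities(factory, x, y, folds, seed)
    return _metrics_from_oof(y, prob)


@dataclass
class PrefixScanCurve:
    """Metrics per ranked-prefix length, and the chosen optimum.

    ``chosen_length`` is the smallest length attaining the maximum
    cross-validated accuracy over the scanned range.
    """

    lengths: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray
    chosen_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": self.lengths,
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "auc": self.auc,
            }
        )


def incremental_selection(
    ranked_features: np.ndarray,
    labels,
    *,
    max_prefix: int = 100,
    folds: int = DEFAULT_FOLDS,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> PrefixScanCurve:
    """Scan ranked-feature prefixes of growing length.

    ``ranked_features`` must already be column-ordered by the stage-1
    ranking (best feature first).  Prefixes 1..min(max_prefix, L) are each
    evaluated by :func:`evaluate_feature_prefix`; the smallest length with
    maximal accuracy is chosen.
    """
    x = np.asarray(ranked_features, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("ranked feature matrix must be (n_subjects, L>=1)")
    l_max = min(max_prefix, x.shape[1])
    rows = []
    for length in range(1, l_max + 1):
        m = evaluate_feature_prefix(
            x[:, :length], labels, folds=folds, grid=grid, seed=seed
        )
        rows.append((length, m.accuracy, m.sensitivity, m.specificity, m.auc))
    arr = np.array(rows)
    acc = arr[:, 1]
    chosen = int(arr[int(np.argmax(acc)), 0])  # argmax returns first (smallest) max
    return PrefixScanCurve(
        lengths=arr[:, 0].astype(int),
        accuracy=acc,
        sensitivity=arr[:, 2],
        specificity=arr[:, 3],
        auc=arr[:, 4],
        chosen_length=chosen,
    )


def concatenate_prefixes(
    smri_ranked: np.ndarray,
    fmri_ranked: np.ndarray,
    smri_length: int,
    fmri_length: int,
) -> np.ndarray:
    """Concatenate the optimal per-modality prefixes into one global vector.

    With the study's optima of 34 structural and 4 connectivity features
    this yields a 38-column fused matrix.
    """
    s = np.asarray(smri_ranked, dtype=float)
    f = np.asarray(fmri_ranked, dtype=float)
    if smri_length < 1 or fmri_length < 1:
        raise ValueError("both modality prefixes must be non-empty")
    if smri_length > s.shape[1] or fmri_length > f.shape[1]:
        raise ValueError("prefix length exceeds available ranked features")
    if s.shape[0] != f.shape[0]:
        raise ValueError(
            f"modalities cover different subject sets: {s.shape[0]} vs {f.shape[0]} rows"
        )
    return np.hstack([s[:, :smri_length], f[:, :fmri_length]])


@dataclass
class FusionModel:
    """The fused global classifier and its cross-validated metrics."""

    smri_length: int
    fmri_length: int
    fused_length: int
    classifier_spec: dict
    metrics: ClassificationMetrics

    def __post_init__(self) -> None:
        if self.fused_length != self.smri_length + self.fmri_length:
            raise ValueError("fused_length must equal the sum of the prefix lengths")


def fuse_modalities(
    smri_curve: PrefixScanCurve,
    fmri_curve: PrefixScanCurve,
    smri_ranked: np.ndarray,
    fmri_ranked: np.ndarray,
    labels,
    *,
    folds: int = DEFAULT_FOLDS,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> FusionModel:
    """Concatenate the optimal prefixes of both modalities and classify.

    The ranked matrices must cover the same subjects (both modalities
    present) in the same row order.
    """
    fused = concatenate_prefixes(
        smri_ranked, fmri_ranked, smri_curve.chosen_length, fmri_curve.chosen_length
    )
    metrics = evaluate_feature_prefix(fused, labels, folds=folds, grid=grid, seed=seed)
    return FusionModel(
        smri_length=smri_curve.chosen_length,
        fmri_length=fmri_curve.chosen_length,
        fused_length=fused.shape[1],
        classifier_spec={
            "type": "random_forest",
            "criterion": "gini",
            "grid": dict(grid if grid is not None else DEFAULT_GRID),
            "folds": folds,
            "seed": seed,
        },
        metrics=metrics,
    )


def benchmark_classifiers(
    features: np.ndarray,
    labels,
    *,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare classifier families on the fused features under identical CV.

    Families and their (fixed, documented) hyperparameters:
    random forest (100 Gini trees, unbounded depth), RBF-kernel SVM (C = 1;
    AUC from the decision function), Gaussian naive Bayes, and a
    feed-forward network (one hidden layer of 32 units, Adam, max 1000
    epochs).  Returns a metric table indexed by family.
    """
    x = np.asarray(features, dtype=float)
    y = _as_binary_labels(labels)

    def svc_score(est, xt):
        return est.decision_function(xt)

    families: dict[str, tuple] = {
        "random_forest": (
            lambda: RandomForestClassifier(
                n_estimators=100, criterion="gini", random_state=seed, n_jobs=1
            ),
            None,
        ),
        "svm": (lambda: SVC(kernel="rbf", C=1.0, random_state=seed), svc_score),
        "naive_bayes": (lambda: GaussianNB(), None),
        "neural_network": (
            lambda: MLPClassifier(
                hidden_layer_sizes=(32,), max_iter=1000, random_state=seed
            ),
            None,
        ),
    }
    rows = {}
    for name, (factory, score_fn) in families.items():
        prob = _cross_validated_probabilities(factory, x, y, folds, seed, score_fn)
        if score_fn is not None:
            # decision-function scores: threshold at 0 for the confusion table
            m = _metrics_from_oof(y, _sigmoid(prob))
        else:
            m = _metrics_from_oof(y, prob)
        rows[name] = m.as_dict()
    return pd.DataFrame(rows).T[["accuracy", "sensitivity", "specificity", "auc"]]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
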