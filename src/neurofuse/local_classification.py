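"""Stage 1: one KNN classifier per pairwise feature.

Every scalar feature — one functional-connectivity entry or one structural
delta entry — gets its own k-nearest-neighbour classifier (k = 7, absolute
distance on the scalar).  Cross-validated over stratified folds shared by
all features, this yields for each feature an out-of-fold accuracy and, for
each subject, an out-of-fold probability of belonging to the autism class
(the fraction of ASD labels among the k nearest training subjects).

Accuracies rank the features for the stage-2 prefix scan; probabilities
feed the personalized per-region maps.

Because a KNN on a scalar only needs ordered neighbours, the grid is
evaluated with a sort + window trick rather than a full distance matrix:
for each feature the training values are sorted once, each query's k
nearest lie inside the 2k-wide window around its insertion point, and the
window is resolved vectorised across features.  This makes the full
18 224-feature structural grid take seconds rather than minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .ados_stats import fmri_feature_index, smri_feature_index

__all__ = [
    "knn_local_classifier",
    "evaluate_local_grid",
    "LocalGridResult",
    "LocalProbabilityMatrices",
    "local_probability_matrices",
    "rank_features",
]

N_REGIONS = 68
DEFAULT_K = 7
DEFAULT_FOLDS = 4


def _as_binary_labels(labels) -> np.ndarray:
    """ASD -> 1, TD -> 0."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "bif":
        return labels.astype(int)
    y = np.where(labels == "ASD", 1, np.where(labels == "TD", 0, -1))
    if (y < 0).any():
        bad = labels[y < 0][:3]
        raise ValueError(f"labels must be ASD or TD, got {bad!r}")
    return y


def knn_local_classifier(
    train_values,
    train_labels,
    query_value: float,
    k: int = DEFAULT_K,
    *,
    tie_order: np.ndarray | None = None,
) -> float:
    """Autism probability of one query under a single-scalar KNN.

    The probability is the fraction of the k nearest training values (by
    absolute difference) labelled ASD.  Exact distance ties are broken by
    ``tie_order`` (a permutation of training indices; identity if omitted),
    matching the seeded-shuffle convention of the grid evaluator.
    """
    x = np.asarray(train_values, dtype=float)
    y = _as_binary_labels(train_labels)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("train_values and train_labels must be equal-length vectors")
    if k > x.size:
        raise ValueError(f"k={k} exceeds number of training subjects {x.size}")
    if k < 1:
        raise ValueError("k must be positive")
    dist = np.abs(x - float(query_value))
    key = tie_order if tie_order is not None else np.arange(x.size)
    order = np.lexsort((key, dist))
    return float(y[order[:k]].mean())


@dataclass
class LocalGridResult:
    """Out-of-fold accuracy and probabilities for a flat feature grid.

    ``accuracy`` has one entry per feature column; ``probability`` is
    (n_subjects, n_features), each entry the subject's out-of-fold autism
    probability under that feature's KNN.  ``fold_assignment`` records the
    shared fold of every subject.
    """

    accuracy: np.ndarray
    probability: np.ndarray
    fold_assignment: np.ndarray
    k: int


def _window_knn_probabilities(
    train: np.ndarray,
    train_y: np.ndarray,
    test: np.ndarray,
    k: int,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorised per-feature scalar KNN.

    ``train``: (n_features, n_train); ``test``: (n_features, n_test).
    Returns autism probabilities (n_features, n_test).  Distance ties are
    broken by position in a seeded shuffle of the training subjects, the
    same convention as :func:`knn_local_classifier` with ``tie_order``.
    """
    n_feat, n_train = train.shape
    if k > n_train:
        raise ValueError(f"k={k} exceeds fold training size {n_train}")
    perm = rng.permutation(n_train)
    w = min(2 * k, n_train)
    offsets = np.arange(w)
    probs = np.empty((n_feat, test.shape[1]))
    for lo in range(0, n_feat, chunk):
        hi = min(lo + chunk, n_feat)
        tv = train[lo:hi][:, perm]  # shuffled columns = tie-break order
        order = np.argsort(tv, axis=1, kind="stable")
        ts = np.take_along_axis(tv, order, axis=1)
        lab_s = train_y[perm][order]  # (c, n_train)
        q = test[lo:hi]
        c = hi - lo
        pos = np.empty((c, q.shape[1]), dtype=np.int64)
        for f in range(c):
            pos[f] = np.searchsorted(ts[f], q[f])
        base = np.clip(pos - k, 0, n_train - w)
        idx = base[:, :, None] + offsets  # (c, n_test, w)
        cand = np.take_along_axis(ts[:, None, :], idx, axis=2)
        dist = np.abs(cand - q[:, :, None])
        # candidate's tie-break key = its column in the shuffled order
        key = np.take_along_axis(order[:, None, :], idx, axis=2)
        nearest = np.lexsort((key, dist), axis=2)[:, :, :k]
        cand_lab = np.take_along_axis(lab_s[:, None, :], idx, axis=2)
        nn_lab = np.take_along_axis(cand_lab, nearest, axis=2)
        probs[lo:hi] = nn_lab.mean(axis=2)
    return probs


def evaluate_local_grid(
    features: np.ndarray,
    labels,
    *,
    n_folds: int = DEFAULT_FOLDS,
    k: int = DEFAULT_K,
    seed: int = 0,
    resubstitution: bool = False,
) -> LocalGridResult:
    """Cross-validated accuracy and probability for every scalar feature.

    Parameters
    ----------
    features:
        ``(n_subjects, n_features)`` matrix of scalar features.
    labels:
        ASD/TD labels (or 0/1 with 1 = ASD).
    n_folds, k, seed:
        Stratified fold count (shared by all features), neighbour count,
        and the seed fixing folds and distance tie-breaks.
    resubstitution:
        If true, probabilities and accuracies are computed on the full
        training set (each subject may be its own neighbour) instead of
        out-of-fold.  Exists to mimic a training-set evaluation; the
        default out-of-fold estimates are the honest ones.
    """
    x = np.asarray(features, dtype=float)
    y = _as_binary_labels(labels)
    n_subj, n_feat = x.shape
    if y.size != n_subj:
        raise ValueError("labels length must match feature rows")
    rng = np.random.default_rng(seed)
    prob = np.empty((n_subj, n_feat))
    fold_assignment = np.full(n_subj, -1, dtype=int)
    if resubstitution:
        fold_assignment[:] = 0
        prob[:] = _window_knn_probabilities(x.T, y, x.T, k, rng).T
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold_no, (tr, te) in enumerate(skf.split(x, y)):
            if len(np.unique(y[tr])) < 2 or min(np.bincount(y[tr])) < 2:
                raise ValueError(f"fold {fold_no} has fewer than 2 subjects in a class")
            fold_assignment[te] = fold_no
            prob[te] = _window_knn_probabilities(x[tr].T, y[tr], x[te].T, k, rng).T
    pred = prob > 0.5  # probability exactly 0.5 resolves to TD
    accuracy = (pred == (y[:, None] == 1)).mean(axis=0)
    return LocalGridResult(
        accuracy=accuracy, probability=prob, fold_assignment=fold_assignment, k=k
    )


@dataclass
class LocalProbabilityMatrices:
    """Region-indexed view of the local-grid output for both modalities.

    ``P_F`` (n_subjects, 68, 68) and ``acc_F`` (68, 68) hold the
    connectivity probabilities/accuracies, symmetric with NaN diagonal
    (feature (i, j) ≡ (j, i); the diagonal is excluded — ρ = 1 and Δ = 0
    are constant).  ``P_S``/``acc_S`` are the structural analogues with a
    trailing feature-slab axis.
    """

    P_F: np.ndarray | None = None
    acc_F: np.ndarray | None = None
    P_S: np.ndarray | None = None
    acc_S: np.ndarray | None = None


def local_probability_matrices(
    fmri: LocalGridResult | None = None,
    smri: LocalGridResult | None = None,
) -> LocalProbabilityMatrices:
    """Scatter flat grid results back onto region-indexed matrices."""
    iu, ju = np.triu_indices(N_REGIONS, k=1)
    out = LocalProbabilityMatrices()
    if fmri is not None:
        n = fmri.probability.shape[0]
        p = np.full((n, N_REGIONS, N_REGIONS), np.nan)
        a = np.full((N_REGIONS, N_REGIONS), np.nan)
        p[:, iu, ju] = fmri.probability
        p[:, ju, iu] = fmri.probability
        a[iu, ju] = fmri.accuracy
        a[ju, iu] = fmri.accuracy
        out.P_F, out.acc_F = p, a
    if smri is not None:
        n = smri.probability.shape[0]
        p = np.full((n, N_REGIONS, N_REGIONS, 8), np.nan)
        a = np.full((N_REGIONS, N_REGIONS, 8), np.nan)
        probs = smri.probability.reshape(n, 8, -1)
        accs = smri.accuracy.reshape(8, -1)
        for f in range(8):
            p[:, iu, ju, f] = probs[:, f]
            p[:, ju, iu, f] = probs[:, f]
            a[iu, ju, f] = accs[f]
            a[ju, iu, f] = accs[f]
        out.P_S, out.acc_S = p, a
    return out


def rank_features(result: LocalGridResult, modality: str) -> pd.DataFrame:
    """Order a modality's features by descending local accuracy.

    Ties are broken by lexicographic (f, i, j) order, so the ranking is
    deterministic.  Returns the feature-index frame with ``accuracy`` and
    ``rank`` columns plus ``column`` (position in the flat feature matrix).
    """
    if modality == "fMRI":
        index = fmri_feature_index()
    elif modality == "sMRI":
        index = smri_feature_index()
    else:
        raise ValueError(f"unknown modality: {modality!r}")
    acc = np.asarray(result.accuracy, dtype=float)
    if acc.size != len(index):
        raise ValueError(
            f"accuracy length {acc.size} does not match {modality} universe {len(index)}"
        )
    order = np.lexsort(
        (index["j"].to_numpy(), index["i"].to_numpy(), index["f"].to_numpy(), -acc)
    )
    ranked = index.iloc[order].copy()
    ranked["accuracy"] = acc[order]
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["column"] = order
    return ranked.reset_index(drop=True)
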