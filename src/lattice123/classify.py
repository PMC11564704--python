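"""1NN classification, iterative hard majority voting and greedy fusion.

Per channel: six selected feature matrices are classified by a
1-nearest-neighbor, city-block-distance, stratified 10-fold
cross-validation predictor; the six out-of-fold prediction vectors are
fused by iterative hard majority voting (element-wise mode over the top-r
accuracy-sorted vectors, r = 3..6, giving 4 voted vectors) and the single
most accurate of the 10 candidates becomes the channel result.  The
channel results are fused the same way at the collection level (r = 3..59
giving 57 voted vectors, 116 candidates in total).

Fold assignment is seeded and shared across the six per-channel
classifiers so voted vectors combine aligned out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "PredictionVector",
    "VotedVector",
    "ChannelResult",
    "OverallResult",
    "make_folds",
    "knn_cv_predict",
    "ihmv",
    "greedy_select",
    "run_channel",
    "run_overall",
]

_BIG = np.float64(1e30)


@dataclass(frozen=True)
class PredictionVector:
    labels: np.ndarray
    source: str = "classifier"  # classifier | voted
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class VotedVector:
    labels: np.ndarray
    member_count: int
    member_indices: tuple[int, ...] = ()
    source: str = "voted"


@dataclass(frozen=True)
class ChannelResult:
    channel_id: int
    best_vector: PredictionVector
    best_accuracy: float
    chosen_source: str  # e.g. "category-4" or "voted-r5"
    category_accuracies: tuple[float, ...] = ()
    selected_sizes: tuple[int, ...] = ()


@dataclass(frozen=True)
class OverallResult:
    best_vector: PredictionVector
    best_accuracy: float
    chosen_source: str
    n_candidates: int
    contributing_channels: tuple[int, ...]
    channel_accuracies: tuple[float, ...] = ()


def make_folds(labels: Sequence, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment (fold id per epoch).

    Falls back to unstratified folds, with a warning, when some class has
    fewer members than folds.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            f"smallest class has {counts.min()} members (< {n_folds} folds); "
            "falling back to non-stratified folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ids = np.empty(y.size, dtype=np.int64)
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros((y.size, 1)), y)):
        fold_ids[test_idx] = k
    return fold_ids


def _fold_penalty(fold_ids: np.ndarray) -> np.ndarray:
    """(n, n) additive mask barring same-fold neighbors (incl. self)."""
    same = fold_ids[:, None] == fold_ids[None, :]
    return np.where(same, _BIG, 0.0)


def _predict_from_distance(
    dist: np.ndarray, labels: np.ndarray, penalty: np.ndarray
) -> np.ndarray:
    """Out-of-fold 1NN labels from a full pairwise distance matrix."""
    nn = np.argmin(dist + penalty, axis=1)  # ties: lowest index
    return labels[nn]


def nn1_cv_sweep(
    ranked_features: np.ndarray,
    labels: np.ndarray,
    fold_ids: np.ndarray,
    iv: int,
    fv: int,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """CV accuracy of nested column prefixes, sizes iv..fv.

    Accumulates the pairwise L1 distance one column at a time so the whole
    sweep costs O(n^2 * fv).  Returns (accuracies, per-size predictions).
    """
    x = np.asarray(ranked_features, dtype=np.float64)
    y = np.asarray(labels)
    n = x.shape[0]
    penalty = _fold_penalty(fold_ids)
    dist = np.zeros((n, n))
    accs = np.empty(fv - iv + 1)
    preds: list[np.ndarray] = []
    for v in range(1, fv + 1):
        col = x[:, v - 1]
        dist += np.abs(col[:, None] - col[None, :])
        if v >= iv:
            p = _predict_from_distance(dist, y, penalty)
            accs[v - iv] = float(np.mean(p == y))
            preds.append(p)
    return accs, preds


def knn_cv_predict(
    features: np.ndarray,
    labels: Sequence,
    folds: int = 10,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
) -> PredictionVector:
    """Out-of-fold 1NN (city-block) predictions in epoch order."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be (n_epochs, n_columns) aligned to labels")
    if np.unique(y).size < 2:
        raise ValueError("need 2 classes")
    if fold_ids is None:
        fold_ids = make_folds(y, folds, seed)
    from scipy.spatial.distance import cdist

    dist = cdist(x, x, metric="cityblock")
    p = _predict_from_distance(dist, y, _fold_penalty(fold_ids))
    return PredictionVector(labels=p, source="classifier")


def _mode_vote(member_labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Element-wise mode over accuracy-sorted member rows.

    member_labels: (r, n_epochs) integer class indices, rows sorted most
    accurate first.  Ties resolve to the tied label predicted earliest by
    the most accurate member among the tied labels.
    """
    r, n = member_labels.shape
    cols = np.arange(n)
    counts = np.zeros((n_classes, n), dtype=np.int64)
    first = np.full((n_classes, n), r, dtype=np.int64)  # earliest voting row
    for i in range(r):
        row = member_labels[i]
        counts[row, cols] += 1
        first[row, cols] = np.minimum(first[row, cols], i)
    is_max = counts == counts.max(axis=0, keepdims=True)
    # among tied labels prefer the one first predicted by the best member
    pref = np.where(is_max, first, r + 1)
    return np.argmin(pref, axis=0)


def ihmv(
    predictions: Sequence[PredictionVector | np.ndarray],
    labels: Sequence,
    r_min: int = 3,
    r_max: int | None = None,
) -> list[VotedVector]:
    """Iterative hard majority voting.

    Sorts the prediction vectors by accuracy (descending, ties keep input
    order) and, for each r = r_min..r_max, takes the element-wise mode of
    the top-r vectors.  6 inputs yield 4 voted vectors; 59 yield 57.
    """
    mats = [
        np.asarray(p.labels if isinstance(p, PredictionVector) else p)
        for p in predictions
    ]
    y = np.asarray(labels)
    np_count = len(mats)
    if np_count < 3:
        raise ValueError(f"IHMV needs at least 3 prediction vectors, got {np_count}")
    if r_max is None:
        r_max = np_count
    if not (3 <= r_min <= r_max <= np_count):
        raise ValueError("need 3 <= r_min <= r_max <= number of vectors")

    accs = np.array([float(np.mean(m == y)) for m in mats])
    order = np.argsort(-accs, kind="stable")

    classes = np.unique(np.concatenate([np.unique(m) for m in mats] + [np.unique(y)]))
    stacked = np.stack(
        [np.searchsorted(classes, mats[i]) for i in order]
    )  # (np, n_epochs)

    voted = []
    for r in range(r_min, r_max + 1):
        idx = _mode_vote(stacked[:r], classes.size)
        voted.append(
            VotedVector(
                labels=classes[idx],
                member_count=r,
                member_indices=tuple(int(i) for i in order[:r]),
            )
        )
    return voted


def greedy_select(
    candidates: Sequence[PredictionVector | VotedVector],
    labels: Sequence,
) -> tuple[PredictionVector | VotedVector, int, float]:
    """Most accurate candidate; ties go to the earliest in the ordering."""
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    y = np.asarray(labels)
    accs = np.array([float(np.mean(np.asarray(c.labels) == y)) for c in candidates])
    best = int(np.argmax(accs))  # first occurrence on ties
    return candidates[best], best, float(accs[best])


def run_channel(
    epochs: np.ndarray,
    labels: Sequence,
    channel_id: int = 0,
    iv: int = 100,
    fv: int = 512,
    folds: int = 10,
    seed: int = 0,
    nca_max_iter: int = 15,
    topology=None,
    fold_ids: np.ndarray | None = None,
) -> ChannelResult:
    """Full per-channel flow: extract -> select -> classify -> vote -> greedy."""
    from .features import extract_feature_matrix
    from .selection import inca_select

    y = np.asarray(labels)
    try:
        if fold_ids is None:
            fold_ids = make_folds(y, folds, seed)
        feats = extract_feature_matrix(epochs, topology=topology, channel_id=channel_id)
        category_preds: list[PredictionVector] = []
        cat_accs: list[float] = []
        sizes: list[int] = []
        for q in range(feats.shape[0]):
            sel = inca_select(
                feats[q],
                y,
                iv=iv,
                fv=fv,
                folds=folds,
                seed=seed,
                fold_ids=fold_ids,
                nca_max_iter=nca_max_iter,
            )
            category_preds.append(
                PredictionVector(
                    labels=sel.predictions,
                    source="classifier",
                    provenance={"channel": channel_id, "category": q + 1},
                )
            )
            cat_accs.append(sel.cv_accuracy)
            sizes.append(sel.size)
        voted = ihmv(category_preds, y)
        candidates = list(category_preds) + list(voted)
        best, idx, acc = greedy_select(candidates, y)
        source = f"category-{idx + 1}" if idx < 6 else f"voted-r{idx - 6 + 3}"
        return ChannelResult(
            channel_id=channel_id,
            best_vector=PredictionVector(
                labels=np.asarray(best.labels),
                source="classifier" if idx < 6 else "voted",
                provenance={"channel": channel_id, "chosen": source},
            ),
            best_accuracy=acc,
            chosen_source=source,
            category_accuracies=tuple(cat_accs),
            selected_sizes=tuple(sizes),
        )
    except Exception as exc:
        raise RuntimeError(f"channel {channel_id} failed: {exc}") from exc


def run_overall(
    channel_results: Sequence[ChannelResult],
    labels: Sequence,
) -> OverallResult:
    """IHMV + greedy over all channel-wise best vectors (59 -> 116 candidates)."""
    if len(channel_results) < 3:
        raise ValueError("need at least 3 channel results")
    y = np.asarray(labels)
    channel_vecs = [cr.best_vector for cr in channel_results]
    voted = ihmv(channel_vecs, y)
    candidates: list[PredictionVector | VotedVector] = list(channel_vecs) + list(voted)
    best, idx, acc = greedy_select(candidates, y)
    nch = len(channel_results)
    if idx < nch:
        source = f"channel-{channel_results[idx].channel_id}"
        contributing = (channel_results[idx].channel_id,)
    else:
        vv = voted[idx - nch]
        source = f"voted-r{vv.member_count}"
        contributing = tuple(
            channel_results[i].channel_id for i in vv.member_indices
        )
    return OverallResult(
        best_vector=PredictionVector(
            labels=np.asarray(best.labels),
            source="overall",
            provenance={"chosen": source},
        ),
        best_accuracy=acc,
        chosen_source=source,
        n_candidates=len(candidates),
        contributing_channels=contributing,
        channel_accuracies=tuple(cr.best_accuracy for cr in channel_results),
    )
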