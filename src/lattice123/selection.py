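"""Iterative NCA feature selection.

Two stages:

1. :func:`nca_rank` learns a non-negative relevance weight per feature
   column by maximizing the regularized leave-one-out neighborhood
   component analysis objective with per-feature (diagonal) weights and L1
   neighbor distances, then ranks columns by descending weight.  Columns
   are z-scored internally for weight learning only.
2. :func:`inca_select` sweeps nested prefixes of the ranking (sizes
   iv..fv, default 100..512), scores each prefix by 1-nearest-neighbor
   10-fold cross-validation accuracy (city-block distance), and keeps the
   most accurate prefix; ties go to the smallest prefix.

The downstream classifier consumes the selected columns unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .classify import make_folds, nn1_cv_sweep

__all__ = ["RankedFeatureIndex", "SelectedFeatureSet", "nca_rank", "inca_select"]

DEFAULT_IV = 100
DEFAULT_FV = 512


@dataclass(frozen=True)
class RankedFeatureIndex:
    """Feature columns ordered best-first with their learned NCA weights."""

    order: np.ndarray  # permutation of column indices, best first
    weights: np.ndarray  # effective (squared) weight per original column

    def __post_init__(self) -> None:
        d = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(d)):
            raise ValueError("order must be a permutation of all column indices")


@dataclass(frozen=True)
class SelectedFeatureSet:
    """The winning prefix of the ranking with its CV accuracy."""

    indices: np.ndarray
    cv_accuracy: float
    predictions: np.ndarray  # out-of-fold 1NN predictions on the winning prefix
    accuracy_curve: np.ndarray  # accuracy per candidate size iv..fv_eff
    sizes: np.ndarray

    @property
    def size(self) -> int:
        return self.indices.size


def _nca_objective_grad(
    w: np.ndarray,
    absdiff: np.ndarray,
    same_class: np.ndarray,
    lam: float,
) -> tuple[float, np.ndarray]:
    """Negative NCA objective and gradient for L-BFGS minimization.

    absdiff: (n*n, d) float32 per-feature |x_i - x_j|; same_class: (n, n)
    with zero diagonal.  Distance uses squared weights, so w is sign-free.
    """
    n = same_class.shape[0]
    u = (w * w).astype(np.float32)
    dist = (absdiff @ u).reshape(n, n).astype(np.float64)
    np.fill_diagonal(dist, np.inf)
    # row-wise shift for a stable softmax over -dist
    shift = dist.min(axis=1, keepdims=True)
    kern = np.exp(-(dist - shift))
    denom = kern.sum(axis=1, keepdims=True)
    p = kern / denom
    p_i = (p * same_class).sum(axis=1)
    fval = p_i.sum() - lam * float(u.sum())
    coef = p * p_i[:, None] - p * same_class  # (n, n)
    np.fill_diagonal(coef, 0.0)
    inner = absdiff.T @ coef.reshape(-1).astype(np.float32)
    grad = 2.0 * w * inner.astype(np.float64) - 2.0 * lam * w
    return -fval, -grad


def nca_rank(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float | None = None,
    max_iter: int = 15,
) -> RankedFeatureIndex:
    """Rank feature columns by diagonal-NCA relevance weight, best first.

    regularization defaults to 1/n_observations.  Weights are initialized
    to ones, making the ranking deterministic.  Ties in weight break toward
    the lower column index.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = x.shape
    if y.shape != (n,):
        raise ValueError("labels length must match the number of observations")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError(
            "each class needs at least 2 observations for leave-one-out NCA"
        )

    # z-score for weight learning only
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = ((x - mu) / sd).astype(np.float32)

    # per-pair |x_i - x_j| built row-block by row-block (cache-friendly)
    absdiff = np.empty((n * n, d), dtype=np.float32)
    for i in range(n):
        block = absdiff[i * n : (i + 1) * n]
        np.subtract(z[i], z, out=block)
        np.abs(block, out=block)
    same = (y_idx[:, None] == y_idx[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)
    lam = 1.0 / n if regularization is None else float(regularization)

    w0 = np.ones(d)
    res = minimize(
        _nca_objective_grad,
        w0,
        args=(absdiff, same, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    weights = res.x**2
    # stable sort on negated weights: ties break toward lower column index
    order = np.argsort(-weights, kind="stable")
    return RankedFeatureIndex(order=order, weights=weights)


def inca_select(
    features: np.ndarray,
    labels: np.ndarray,
    iv: int = DEFAULT_IV,
    fv: int = DEFAULT_FV,
    folds: int = 10,
    seed: int = 0,
    ranking: RankedFeatureIndex | None = None,
    fold_ids: np.ndarray | None = None,
    nca_max_iter: int = 15,
) -> SelectedFeatureSet:
    """Select the ranked-prefix feature subset with best 1NN CV accuracy.

    Sweeps prefix sizes v = iv..min(fv, n_columns); the sweep silently
    truncates when fv exceeds the column count.  Equal accuracies resolve
    to the smallest prefix.  ``fold_ids`` (or ``seed``) fixes the fold
    assignment so selection and final classification share folds.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    n, d = x.shape
    if d < iv:
        raise ValueError(
            f"only {d} feature columns available but iv={iv}; use a smaller iv"
        )
    if iv < 1 or fv < iv:
        raise ValueError("need 1 <= iv <= fv")
    if ranking is None:
        ranking = nca_rank(x, y, max_iter=nca_max_iter)
    if fold_ids is None:
        fold_ids = make_folds(y, folds, seed)

    fv_eff = min(fv, d)
    ranked = x[:, ranking.order[:fv_eff]]
    accs, preds = nn1_cv_sweep(ranked, y, fold_ids, iv, fv_eff)
    best = int(np.argmax(accs))  # first occurrence = smallest prefix on ties
    sizes = np.arange(iv, fv_eff + 1)
    return SelectedFeatureSet(
        indices=ranking.order[: sizes[best]].copy(),
        cv_accuracy=float(accs[best]),
        predictions=preds[best],
        accuracy_curve=accs,
        sizes=sizes,
    )
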