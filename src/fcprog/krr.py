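"""Kernel ridge regression on a between-subject FC similarity kernel.

Each test subject's outcome is predicted as a regularized weighted mean of
the training outcomes: the kernel entry (i, j) is the Pearson correlation
between subject i's and subject j's FC feature vectors, and the dual weights
solve ``(K + lambda I) a = y - y_bar`` on the training set (the correlation
kernel has no intercept, so the target is centred and the training mean
re-added at prediction time).

The l2 strength ``lambda`` is picked from a grid by an inner loop of 4-fold
cross-validation inside the training set, maximizing the mean inner-fold
Pearson correlation between predictions and targets; ties go to the
smallest grid value.  The default grid spans 16 logarithmically spaced
values from 1e-3 to 1e4 plus 0; a grid value whose regularized kernel is
numerically singular on some inner fold is skipped with a warning rather
than aborting the fit.

Linear systems are solved through an eigendecomposition of the training
kernel, which makes evaluating the whole grid (and whole batches of
permuted targets) cheap: one decomposition serves every lambda and every
target column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._utils import columnwise_pearson, fold_allocation

_EIG_TOL = 1e-10

DEFAULT_LAMBDA_GRID = np.sort(
    np.concatenate(([0.0], np.logspace(-3, 4, 16)))
)


def build_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson-correlation similarity between rows of A and rows of B.

    ``build_kernel(A, A)`` is symmetric with unit diagonal.  A subject with a
    constant feature vector makes the correlation undefined and raises an
    error naming that subject.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature (edge) dimensions of A and B differ")
    if A.shape[1] < 2:
        raise ValueError("similarity needs at least 2 edges")
    for name, M in (("A", A), ("B", B)):
        flat = np.flatnonzero(np.ptp(M, axis=1) == 0)
        if flat.size:
            raise ValueError(
                f"subject {flat[0]} of {name} has a constant feature vector; "
                "similarity is undefined"
            )
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Ac /= np.linalg.norm(Ac, axis=1, keepdims=True)
    Bc /= np.linalg.norm(Bc, axis=1, keepdims=True)
    K = Ac @ Bc.T
    K = np.clip(K, -1.0, 1.0)
    if A.shape == B.shape and np.shares_memory(A, B) or (
        A.shape == B.shape and np.array_equal(A, B)
    ):
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
    return K


@dataclass
class KernelModel:
    """A fitted correlation-kernel ridge regressor."""

    kernel_kind: str
    lam: float
    lambda_grid: np.ndarray
    dual_weights: np.ndarray
    X_train: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    inner_scores: np.ndarray | None = field(default=None, repr=False)


def _select_lambda(
    K: np.ndarray,
    Y: np.ndarray,
    inner_ids: np.ndarray,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Inner-CV mean correlation per (lambda, target); returns best indices.

    A lambda is excluded (score -inf, with a warning) when ``K + lambda I``
    is numerically singular on any inner training fold.  Best index per
    target is the first maximum over the ascending grid, i.e. ties break
    toward the smallest lambda.
    """
    n_grid = grid.size
    P = Y.shape[1]
    folds = np.unique(inner_ids)
    scores = np.zeros((n_grid, P))
    invalid = np.zeros(n_grid, dtype=bool)
    for g in folds:
        ite = inner_ids == g
        itr = ~ite
        w, U = linalg.eigh(K[np.ix_(itr, itr)])
        Yt = Y[itr]
        mu = Yt.mean(axis=0)
        Uty = U.T @ (Yt - mu)
        Kte = K[np.ix_(ite, itr)]
        for gi, lam in enumerate(grid):
            if w.min() + lam < _EIG_TOL:
                invalid[gi] = True
                continue
            alpha = U @ (Uty / (w + lam)[:, None])
            pred = Kte @ alpha + mu
            scores[gi] += columnwise_pearson(pred, Y[ite])
    if invalid.any():
        warnings.warn(
            f"skipped {int(invalid.sum())} singular lambda value(s) in the "
            "inner CV loop",
            stacklevel=2,
        )
    if invalid.all():
        raise np.linalg.LinAlgError("every lambda in the grid is singular")
    scores /= folds.size
    scores[invalid] = -np.inf
    return np.argmax(scores, axis=0), scores


def _solve(
    K: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dual weights and training means for (K + lam I) a = Y - mean(Y)."""
    w, U = linalg.eigh(K)
    if w.min() + lam < _EIG_TOL:
        raise np.linalg.LinAlgError(
            f"K + {lam} I is numerically singular"
        )
    mu = Y.mean(axis=0)
    alpha = U @ ((U.T @ (Y - mu)) / (w + lam)[:, None])
    return alpha, mu


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    inner_folds: int = 4,
    seed: int = 0,
) -> KernelModel:
    """Tune lambda by inner cross-validation, then solve on all of (X, y).

    The seeded inner-fold allocation is the only randomness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2 * inner_folds:
        raise ValueError(
            f"need at least {2 * inner_folds} training subjects for "
            f"{inner_folds} non-trivial inner folds"
        )
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; correlation undefined")
    grid = (
        DEFAULT_LAMBDA_GRID if lambda_grid is None
        else np.sort(np.asarray(lambda_grid, dtype=float))
    )
    K = build_kernel(X, X)
    inner_scores = None
    if grid.size == 1:
        lam = float(grid[0])
    else:
        rng = np.random.default_rng(seed)
        inner_ids = fold_allocation(X.shape[0], inner_folds, rng)
        best, inner_scores = _select_lambda(K, y[:, None], inner_ids, grid)
        lam = float(grid[best[0]])
    alpha, mu = _solve(K, y[:, None], lam)
    return KernelModel(
        kernel_kind="pearson_similarity",
        lam=lam,
        lambda_grid=grid,
        dual_weights=alpha[:, 0],
        X_train=X,
        y_mean=float(mu[0]),
        inner_scores=inner_scores,
    )


def predict(model: KernelModel, X: np.ndarray) -> np.ndarray:
    """Weighted mean of training outcomes: k_test . a + training mean."""
    k = build_kernel(np.atleast_2d(X), model.X_train)
    return k @ model.dual_weights + model.y_mean


def cv_split_predictions(
    K: np.ndarray,
    Y: np.ndarray,
    fold_ids: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    inner_folds: int = 4,
) -> np.ndarray:
    """Out-of-fold KRR predictions for many target columns at once.

    ``K`` is the precomputed all-subject similarity kernel (it does not
    depend on the fold allocation, so it is built once per cohort).  Lambda
    is tuned per outer fold and per target column by the same inner-CV rule
    as :func:`fit`; ``rng`` drives the inner-fold allocations.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be subjects x targets")
    grid = (
        DEFAULT_LAMBDA_GRID if lambda_grid is None
        else np.sort(np.asarray(lambda_grid, dtype=float))
    )
    if rng is None:
        rng = np.random.default_rng(0)
    n, P = Y.shape
    preds = np.empty((n, P))
    for f in np.unique(fold_ids):
        te = fold_ids == f
        tr = ~te
        idx_tr = np.flatnonzero(tr)
        K_tr = K[np.ix_(idx_tr, idx_tr)]
        Y_tr = Y[tr]
        if grid.size == 1:
            best = np.zeros(P, dtype=int)
        else:
            inner_ids = fold_allocation(idx_tr.size, inner_folds, rng)
            best, _ = _select_lambda(K_tr, Y_tr, inner_ids, grid)
        w, U = linalg.eigh(K_tr)
        K_te = K[np.ix_(np.flatnonzero(te), idx_tr)]
        mu = Y_tr.mean(axis=0)
        Uty = U.T @ (Y_tr - mu)
        for gi in np.unique(best):
            lam = grid[gi]
            cols = best == gi
            if w.min() + lam < _EIG_TOL:
                # singular at the chosen lambda on the full fold: fall back
                # to the training mean (degenerate but defined)
                preds[np.ix_(te, cols)] = mu[cols]
                continue
            alpha = U @ (Uty[:, cols] / (w + lam)[:, None])
            preds[np.ix_(te, cols)] = K_te @ alpha + mu[cols]
    return preds
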