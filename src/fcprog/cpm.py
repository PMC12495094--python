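"""Connectome-based predictive modelling (CPM).

CPM predicts a continuous outcome from a connectivity feature matrix in
three deterministic steps, all confined to the training set:

1. univariate feature selection — an edge is kept when the Pearson
   correlation between its values and the outcome has the requested sign
   and a two-sided p-value below ``alpha`` (exact t transform,
   ``t = r * sqrt((n - 2) / (1 - r^2))`` with n-2 degrees of freedom);
2. a summary score per subject — the sum of that subject's FC values over
   the selected edges (0 for an empty selection);
3. a one-variable least-squares line from summary score to outcome.

If no edge survives selection, or the summary scores are constant, the model
degenerates to predicting the training mean — the standard CPM convention
that keeps every cross-validation split well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def correlation_threshold(alpha: float, n: int) -> float:
    """|r| above which the two-sided p-value of a Pearson r is below alpha.

    The t transform is monotone in |r|, so thresholding |r| against this
    value is exactly equivalent to thresholding the p-value against alpha.
    Returns 1.0 for alpha <= 0 (nothing selectable) and 0.0 for alpha >= 1.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if alpha <= 0:
        return 1.0
    if alpha >= 1:
        return 0.0
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _column_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of X with y; constant columns get r = 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    yn = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (xn * yn)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def select_features(
    X: np.ndarray, y: np.ndarray, sign: str, alpha: float = 0.05
) -> np.ndarray:
    """Indices of edges whose correlation with y has ``sign`` and p < alpha.

    ``sign`` is ``"positive"`` (r > 0) or ``"negative"`` (r < 0); the
    p-value is always two-sided, so the sign and significance conditions are
    checked separately.  Constant edge columns are excluded with a warning
    (their correlation is undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("feature selection needs at least 4 subjects")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; correlation undefined")
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant edge column(s) from "
            "selection",
            stacklevel=2,
        )
    r = _column_correlations(X, y)
    r_crit = correlation_threshold(alpha, n)
    if sign == "positive":
        keep = (r > 0) & (r > r_crit)
    else:
        keep = (r < 0) & (-r > r_crit)
    keep &= ~constant
    return np.flatnonzero(keep)


def summary_score(x: np.ndarray, selected_edges: np.ndarray) -> np.ndarray | float:
    """Sum of FC values over the selected edges; empty selection sums to 0.

    Accepts one subject's feature vector (returns a float) or a
    subjects-by-edges matrix (returns a vector).
    """
    x = np.asarray(x, dtype=float)
    idx = np.asarray(selected_edges, dtype=int)
    if x.ndim == 1:
        return float(x[idx].sum())
    return x[:, idx].sum(axis=1)


@dataclass
class CPMModel:
    """A fitted CPM: selected edges plus the summary-score line."""

    selected_edges: np.ndarray
    sign: str
    alpha: float
    intercept: float
    slope: float
    training_r: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_degenerate(self) -> bool:
        return self.slope == 0.0 and self.selected_edges.size == 0


def _line_fit(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of y on scores; constant scores fall back to the mean."""
    sc = scores - scores.mean()
    denom = sc @ sc
    if denom == 0:
        return float(y.mean()), 0.0
    slope = float(sc @ (y - y.mean()) / denom)
    return float(y.mean() - slope * scores.mean()), slope


def fit(
    X: np.ndarray, y: np.ndarray, sign: str, alpha: float = 0.05
) -> CPMModel:
    """Select features on (X, y) and fit the summary-score line."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    selected = select_features(X, y, sign, alpha)
    scores = np.asarray(summary_score(X, selected))
    if selected.size == 0:
        intercept, slope = float(y.mean()), 0.0
    else:
        intercept, slope = _line_fit(scores, y)
    r = _column_correlations(X, y)
    return CPMModel(
        selected_edges=selected,
        sign=sign,
        alpha=alpha,
        intercept=intercept,
        slope=slope,
        training_r=r,
    )


def predict(model: CPMModel, X: np.ndarray) -> np.ndarray:
    """intercept + slope * summary score, per test subject."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = np.asarray(summary_score(X, model.selected_edges))
    return model.intercept + model.slope * scores


def export_edges(
    model: CPMModel, edge_index: np.ndarray, path
) -> None:
    """Write selected edges as an (i, j, r) text file."""
    with open(path, "w") as fh:
        fh.write("i\tj\tr\n")
        for e in model.selected_edges:
            r = model.training_r[e] if model.training_r is not None else np.nan
            fh.write(f"{edge_index[0, e]}\t{edge_index[1, e]}\t{r:.6f}\n")


def cv_split_predictions(
    X: np.ndarray,
    Y: np.ndarray,
    fold_ids: np.ndarray,
    sign: str,
    alpha: float = 0.05,
) -> np.ndarray:
    """Out-of-fold CPM predictions for many target columns at once.

    ``Y`` is subjects x targets; each column is treated as an independent
    outcome (the batched path used for permutation nulls).  For every fold,
    selection, the summary-score line and prediction are computed entirely
    from the training subjects, vectorized across target columns.  The
    single-target path ``fit``/``predict`` gives identical results column by
    column.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be subjects x targets")
    n, n_targets = Y.shape
    preds = np.empty((n, n_targets))
    for f in np.unique(fold_ids):
        te = fold_ids == f
        tr = ~te
        Xtr, Ytr = X[tr], Y[tr]
        n_tr = Xtr.shape[0]
        r_crit = correlation_threshold(alpha, n_tr)
        Xc = Xtr - Xtr.mean(axis=0)
        Yc = Ytr - Ytr.mean(axis=0)
        xn = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
        yn = np.sqrt(np.einsum("ij,ij->j", Yc, Yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Xc.T @ Yc) / np.outer(xn, yn)
        R[~np.isfinite(R)] = 0.0
        if sign == "positive":
            S = R > r_crit
        else:
            S = R < -r_crit
        scores_tr = Xtr @ S          # n_tr x targets summary scores
        scores_te = X[te] @ S
        sc = scores_tr - scores_tr.mean(axis=0)
        denom = np.einsum("ij,ij->j", sc, sc)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.einsum("ij,ij->j", sc, Yc) / denom
        slope[~np.isfinite(slope)] = 0.0
        slope[denom == 0] = 0.0
        intercept = Ytr.mean(axis=0) - slope * scores_tr.mean(axis=0)
        preds[te] = intercept + slope * scores_te
    return preds
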