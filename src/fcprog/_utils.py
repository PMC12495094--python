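"""Shared numerical helpers: fold allocation and column-wise correlation."""

from __future__ import annotations

import numpy as np


def fold_allocation(
    n: int, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random partition of n subjects into folds with sizes differing by <= 1.

    Returns an integer fold id per subject.  Uniform random allocation, no
    stratification on the outcome.
    """
    if n < n_folds:
        raise ValueError(f"cannot split {n} subjects into {n_folds} folds")
    ids = np.resize(np.arange(n_folds), n)
    return ids[rng.permutation(n)]


def columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of A and B.

    Columns where either side is constant get r = 0 (the degenerate-
    prediction convention used throughout the evaluation machinery).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    an = np.sqrt(np.einsum("ij,ij->j", Ac, Ac))
    bn = np.sqrt(np.einsum("ij,ij->j", Bc, Bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", Ac, Bc) / (an * bn)
    r[~np.isfinite(r)] = 0.0
    r[(np.ptp(A, axis=0) == 0) | (np.ptp(B, axis=0) == 0)] = 0.0
    return np.clip(r, -1.0, 1.0)
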