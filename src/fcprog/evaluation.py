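"""Repeated-split cross-validated evaluation with permutation inference.

Every prognostic model is scored the same way: subjects are partitioned at
random into 4 folds, each fold is predicted once from a model trained on
the other three, the pooled out-of-fold predictions are correlated with the
observed targets (one Pearson r per split), and the procedure is repeated
over many random splits.  The headline statistic is ``r_mean``, the mean of
the per-split correlations.

Significance comes from permutation testing: targets are shuffled among
subjects with a fixed seed, the full pipeline (feature selection and
hyperparameter tuning included, strictly inside training folds) is re-run
per permutation with a per-algorithm split budget, and the p-value is the
proportion of null r_mean values at or above the observed one.  Familywise
error across the models sharing an algorithm is controlled by the
Westfall-Young max-statistic method: the null distribution at each
permutation is the maximum r_mean across the algorithm's models.

Permutations are evaluated batched: at a given split, every shuffled target
column shares that split's fold allocation (and the inner-CV allocations),
which preserves exactness of the permutation p-value — the shuffled targets
are exchangeable conditional on the allocation — while allowing a
1000-permutation run to reduce to a handful of matrix products per split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import connectome, cpm, krr
from ._utils import columnwise_pearson, fold_allocation

CPM = "cpm"
KRR = "krr"
METAMATCH = "metamatch"
ALGORITHMS = (CPM, KRR, METAMATCH)

MEASURES = ("functioning", "symptoms")
TIMEPOINTS = (6, 12)
PREDICTORS = (connectome.BASELINE_FC, connectome.DELTA_FC)
SIGNS = ("positive", "negative")

# per-algorithm split budgets for permutation null models
DEFAULT_PERM_SPLITS = {CPM: 100, KRR: 50, METAMATCH: 20}


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial model grid."""

    algorithm: str
    measure: str
    timepoint: int
    predictor: str
    sign: str | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError("timepoint must be 6 or 12")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if (self.sign is not None) != (self.algorithm == CPM):
            raise ValueError("sign is set if and only if the algorithm is CPM")
        if self.sign is not None and self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")
        if self.algorithm == METAMATCH and self.predictor != connectome.BASELINE_FC:
            raise ValueError(
                "meta-matching supports only the baseline-FC predictor"
            )

    def label(self) -> str:
        parts = [self.algorithm, self.measure, f"{self.timepoint}m", self.predictor]
        if self.sign is not None:
            parts.append(self.sign)
        return "/".join(parts)


@dataclass(frozen=True)
class SplitScheme:
    """Repeated random 4-fold split plan."""

    n_folds: int = 4
    n_splits: int = 100
    base_seed: int = 0


@dataclass
class EvaluationResult:
    """Per-split correlations and, once computed, permutation inference."""

    spec: ModelSpec
    n: int
    r_per_split: np.ndarray
    null_rmeans: np.ndarray | None = field(default=None, repr=False)
    p: float | None = None
    p_fwe: float | None = None

    @property
    def r_mean(self) -> float:
        return float(self.r_per_split.mean())


def enumerate_models(algorithm: str, alpha: float = 0.05) -> list[ModelSpec]:
    """The full factorial model grid of one algorithm.

    CPM: measure x timepoint x predictor x sign = 16 models; KRR: measure x
    timepoint x predictor = 8; meta-matching: measure x timepoint = 4
    (baseline FC only).
    """
    if algorithm == CPM:
        return [
            ModelSpec(CPM, m, t, p, sign=s, alpha=alpha)
            for m, t, p, s in itertools.product(
                MEASURES, TIMEPOINTS, PREDICTORS, SIGNS
            )
        ]
    if algorithm == KRR:
        return [
            ModelSpec(KRR, m, t, p)
            for m, t, p in itertools.product(MEASURES, TIMEPOINTS, PREDICTORS)
        ]
    if algorithm == METAMATCH:
        return [
            ModelSpec(METAMATCH, m, t, connectome.BASELINE_FC)
            for m, t in itertools.product(MEASURES, TIMEPOINTS)
        ]
    raise ValueError(f"unknown algorithm {algorithm!r}")


class Engine:
    """Out-of-fold prediction engine for one (spec, feature matrix) pair.

    Precomputes whatever does not depend on the fold allocation (the
    similarity kernel for KRR and meta-matching) and exposes a batched
    ``predictions`` over many target columns, which is what makes large
    permutation runs cheap.
    """

    def __init__(
        self,
        spec: ModelSpec,
        X: np.ndarray,
        lambda_grid: np.ndarray | None = None,
    ) -> None:
        self.spec = spec
        self.X = np.asarray(X, dtype=float)
        self.lambda_grid = lambda_grid
        self._K = None
        if spec.algorithm in (KRR, METAMATCH):
            self._K = krr.build_kernel(self.X, self.X)

    def predictions(
        self, Y: np.ndarray, fold_ids: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        if self.spec.algorithm == CPM:
            return cpm.cv_split_predictions(
                self.X, Y, fold_ids, self.spec.sign, self.spec.alpha
            )
        return krr.cv_split_predictions(
            self._K, Y, fold_ids, self.lambda_grid, rng
        )

    def split_correlations(
        self, Y: np.ndarray, fold_ids: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        return columnwise_pearson(self.predictions(Y, fold_ids, rng), Y)


def _split_rngs(scheme: SplitScheme, s: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Fold-allocation rng and inner-CV rng for split s."""
    return (
        np.random.default_rng([scheme.base_seed, s]),
        np.random.default_rng([scheme.base_seed, s, 1]),
    )


def run_split(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    fold_assignment: np.ndarray,
    rng: np.random.Generator | None = None,
    lambda_grid: np.ndarray | None = None,
) -> float:
    """One split: pooled out-of-fold predictions, one Pearson r.

    Constant pooled predictions make the correlation undefined; the split
    scores 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 subjects for a 4-fold split")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; correlation undefined")
    if rng is None:
        rng = np.random.default_rng(0)
    engine = Engine(spec, X, lambda_grid)
    preds = engine.predictions(y[:, None], np.asarray(fold_assignment), rng)
    if np.ptp(preds[:, 0]) == 0:
        warnings.warn(
            f"{spec.label()}: constant pooled predictions; split scored 0",
            stacklevel=2,
        )
    return float(columnwise_pearson(preds, y[:, None])[0])


def evaluate_model(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    lambda_grid: np.ndarray | None = None,
    engine: Engine | None = None,
) -> EvaluationResult:
    """r per split and r_mean over ``scheme.n_splits`` repeated splits."""
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; correlation undefined")
    if engine is None:
        engine = Engine(spec, X, lambda_grid)
    n = y.size
    r = np.empty(scheme.n_splits)
    for s in range(scheme.n_splits):
        rng_alloc, rng_inner = _split_rngs(scheme, s)
        fold_ids = fold_allocation(n, scheme.n_folds, rng_alloc)
        r[s] = engine.split_correlations(y[:, None], fold_ids, rng_inner)[0]
    return EvaluationResult(spec=spec, n=n, r_per_split=r)


def shuffled_targets(
    y: np.ndarray, n_perm: int, perm_seed: int
) -> np.ndarray:
    """n_perm seeded random shuffles of y, as a subjects x n_perm matrix."""
    rng = np.random.default_rng(perm_seed)
    y = np.asarray(y, dtype=float)
    return np.column_stack([y[rng.permutation(y.size)] for _ in range(n_perm)])


def permutation_test(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    n_perm: int = 1000,
    perm_splits: int | None = None,
    perm_seed: int = 0,
    plus_one: bool = False,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation null of r_mean and the resulting p-value.

    Each permutation shuffles the targets among subjects and re-runs the
    full pipeline with ``perm_splits`` splits (defaulting to the
    per-algorithm budget: 100 for CPM, 50 for KRR, 20 for meta-matching).
    ``p`` is the proportion of null r_mean values >= the observed r_mean
    (ties count against the observed value); ``plus_one`` switches to the
    (k+1)/(n+1) estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if perm_splits is None:
        perm_splits = DEFAULT_PERM_SPLITS[spec.algorithm]
    engine = Engine(spec, X, lambda_grid)
    observed = evaluate_model(spec, X, y, scheme, engine=engine)
    Y = shuffled_targets(y, n_perm, perm_seed)
    null_sum = np.zeros(n_perm)
    n = y.size
    for s in range(perm_splits):
        rng_alloc, rng_inner = _split_rngs(scheme, s)
        fold_ids = fold_allocation(n, scheme.n_folds, rng_alloc)
        null_sum += engine.split_correlations(Y, fold_ids, rng_inner)
    null_rmeans = null_sum / perm_splits
    p = _p_value(null_rmeans, observed.r_mean, plus_one)
    return null_rmeans, p


def _p_value(null: np.ndarray, observed: float, plus_one: bool) -> float:
    k = int(np.sum(null >= observed))
    if plus_one:
        return (k + 1) / (null.size + 1)
    return k / null.size


def westfall_young(
    null_matrix: np.ndarray,
    observed: np.ndarray,
    plus_one: bool = False,
) -> np.ndarray:
    """Max-statistic familywise-corrected p-values.

    ``null_matrix`` is permutations x models (all models sharing one
    algorithm, grouped by permutation index); the familywise null value at
    permutation k is the maximum across that row, and each model's p_FWE is
    the proportion of familywise null values >= its observed r_mean.  By
    construction p_FWE >= p for every model.
    """
    null_matrix = np.asarray(null_matrix, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if null_matrix.ndim != 2 or null_matrix.shape[1] != observed.size:
        raise ValueError(
            f"null matrix shape {null_matrix.shape} does not match "
            f"{observed.size} observed values"
        )
    fwe_null = null_matrix.max(axis=1)
    return np.array([_p_value(fwe_null, o, plus_one) for o in observed])
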