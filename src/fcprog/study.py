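"""Study-level orchestration: a model object over a cohort, fitted results.

:class:`PredictionStudy` is built from cohort data (feature matrices per
predictor plus the clinical outcome table); its :meth:`~PredictionStudy.fit`
runs the factorial model grid — every algorithm x measure x timepoint x
predictor (x sign) cell — through repeated-split cross-validation and,
optionally, permutation inference with Westfall-Young familywise
correction, returning a :class:`StudyResults` that carries the per-model
r_mean / p / p_FWE table, per-split correlation distributions, a
``summary()`` and plotting/saving helpers.

Subjects entering each cell are the intersection of those with the required
predictor (baseline scan, or both scans for delta-FC) and the required
outcome visits; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome, evaluation, metamatch, outcomes, simulate
from .evaluation import (
    ALGORITHMS,
    DEFAULT_PERM_SPLITS,
    METAMATCH,
    EvaluationResult,
    ModelSpec,
    SplitScheme,
)


@dataclass
class StudyResults:
    """Fitted results of a :class:`PredictionStudy`."""

    results: list[EvaluationResult]
    scheme: SplitScheme
    n_perm: int = 0

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            s = res.spec
            rows.append(
                {
                    "algorithm": s.algorithm,
                    "measure": s.measure,
                    "timepoint": s.timepoint,
                    "predictor": s.predictor,
                    "sign": s.sign if s.sign is not None else "n/a",
                    "n": res.n,
                    "r_mean": res.r_mean,
                    "p": res.p,
                    "p_fwe": res.p_fwe,
                }
            )
        return pd.DataFrame(rows)

    def splits_long(self) -> pd.DataFrame:
        """Per-split correlations in long format (one row per model x split)."""
        frames = []
        for res in self.results:
            frames.append(
                pd.DataFrame(
                    {
                        "model": res.spec.label(),
                        "split": np.arange(res.r_per_split.size),
                        "r": res.r_per_split,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable study table."""
        t = self.table.copy()
        t["r_mean"] = t["r_mean"].map(lambda v: f"{v: .3f}")
        for col in ("p", "p_fwe"):
            t[col] = t[col].map(
                lambda v: "-" if v is None or pd.isna(v) else f"{v:.3f}"
            )
        lines = [
            "Prognostic model evaluation "
            f"({self.scheme.n_splits} splits of {self.scheme.n_folds}-fold CV"
            + (f", {self.n_perm} permutations)" if self.n_perm else ")"),
            "=" * 78,
            t.to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "results.csv", index=False)
        self.splits_long().to_csv(directory / "split_correlations.csv", index=False)
        return directory

    def plot_split_distributions(self, path: str | Path | None = None):
        """Strip plot of per-split correlations, one column per model."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        long = self.splits_long()
        models = list(dict.fromkeys(long["model"]))
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(models)), 4))
        rng = np.random.default_rng(0)
        for i, m in enumerate(models):
            r = long.loc[long["model"] == m, "r"]
            ax.scatter(
                i + rng.uniform(-0.15, 0.15, r.size), r, s=6, alpha=0.5
            )
            ax.plot([i - 0.25, i + 0.25], [r.mean()] * 2, color="k", lw=2)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xticks(range(len(models)))
        ax.set_xticklabels(models, rotation=90, fontsize=7)
        ax.set_ylabel("per-split r (predicted vs observed)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


class PredictionStudy:
    """Factorial prognostic-modelling study over one cohort.

    Parameters
    ----------
    baseline_features, baseline_ids
        Subjects-by-edges baseline FC matrix and the matching subject ids.
    delta_features, delta_ids
        Same for the delta-FC predictor (subjects with both scans); may be
        omitted, in which case delta-FC cells are skipped.
    outcome_table
        Longitudinal clinical scores.
    bank
        Optional trained :class:`~fcprog.metamatch.ProxyBank`; required for
        meta-matching cells (or trained on synthetic source cohorts via
        ``with_default_bank``).
    """

    def __init__(
        self,
        baseline_features: np.ndarray,
        baseline_ids: list[str],
        outcome_table: outcomes.OutcomeTable,
        delta_features: np.ndarray | None = None,
        delta_ids: list[str] | None = None,
        bank: metamatch.ProxyBank | None = None,
        lambda_grid: np.ndarray | None = None,
        use_fisher_z: bool = False,
    ) -> None:
        def maybe_z(x):
            return connectome.fisher_z(x) if use_fisher_z else x

        self._features: dict[str, tuple[np.ndarray, list[str]]] = {
            connectome.BASELINE_FC: (
                maybe_z(np.asarray(baseline_features, float)),
                list(baseline_ids),
            )
        }
        if delta_features is not None:
            self._features[connectome.DELTA_FC] = (
                np.asarray(delta_features, float),
                list(delta_ids),
            )
        self.outcome_table = outcome_table
        self.bank = bank
        self.lambda_grid = lambda_grid
        self._proxies: np.ndarray | None = None

    # ----- constructors ---------------------------------------------------

    @classmethod
    def from_cohort(
        cls, cohort: simulate.SyntheticCohort, **kwargs
    ) -> "PredictionStudy":
        Xb, ids_b = cohort.baseline_fc_vectors()
        Xd, ids_d = cohort.delta_fc_vectors()
        return cls(
            baseline_features=Xb,
            baseline_ids=ids_b,
            outcome_table=cohort.outcome_table,
            delta_features=Xd,
            delta_ids=ids_d,
            **kwargs,
        )

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "PredictionStudy":
        return cls.from_cohort(simulate.load_cohort(directory), **kwargs)

    def with_default_bank(
        self, n_regions: int, seed: int = 0, n_source_subjects: int = 2000
    ) -> "PredictionStudy":
        """Train the synthetic default proxy bank (5 base + 10 extra phenotypes)."""
        cohorts, _ = metamatch.simulate_source_cohorts(
            n_regions=n_regions, n_subjects=n_source_subjects, seed=seed
        )
        self.bank = metamatch.train_bank(cohorts, seed=seed)
        self._proxies = None
        return self

    # ----- fitting --------------------------------------------------------

    def _proxy_features(self) -> tuple[np.ndarray, list[str]]:
        if self.bank is None:
            raise ValueError(
                "meta-matching requires a trained proxy bank; pass bank= or "
                "call with_default_bank()"
            )
        X, ids = self._features[connectome.BASELINE_FC]
        if self._proxies is None:
            proxies = metamatch.generate_proxies(self.bank, X).values
            keep = np.ptp(proxies, axis=0) > 0
            self._proxies = proxies[:, keep]
        return self._proxies, ids

    def _cell_data(
        self, spec: ModelSpec, outcome_kind: str
    ) -> tuple[np.ndarray, np.ndarray] | None:
        if spec.algorithm == METAMATCH:
            X, ids = self._proxy_features()
        else:
            if spec.predictor not in self._features:
                return None
            X, ids = self._features[spec.predictor]
        targets = outcomes.build_targets(
            self.outcome_table, spec.measure, spec.timepoint, outcome_kind
        )
        mask = np.array([sid in targets.index for sid in ids])
        if mask.sum() < 8:
            return None
        y = targets.loc[[sid for sid, m in zip(ids, mask) if m]].to_numpy()
        return X[mask], y

    def fit(
        self,
        algorithms: tuple[str, ...] = ALGORITHMS,
        scheme: SplitScheme = SplitScheme(),
        n_perm: int = 0,
        perm_splits: dict[str, int] | None = None,
        perm_seed: int = 0,
        outcome_kind: str = outcomes.PROPORTIONAL_CHANGE,
        alpha: float = 0.05,
        plus_one: bool = False,
    ) -> StudyResults:
        """Run the model grid; with ``n_perm > 0`` add permutation inference.

        Failures in individual cells (too few subjects, degenerate data) are
        recorded by skipping the cell; the run continues.
        """
        if perm_splits is None:
            perm_splits = DEFAULT_PERM_SPLITS
        all_results: list[EvaluationResult] = []
        for algorithm in algorithms:
            specs = evaluation.enumerate_models(algorithm, alpha=alpha)
            cell_results: list[EvaluationResult] = []
            nulls: list[np.ndarray] = []
            for spec in specs:
                data = self._cell_data(spec, outcome_kind)
                if data is None:
                    continue
                X, y = data
                if n_perm > 0:
                    engine = evaluation.Engine(spec, X, self.lambda_grid)
                    res = evaluation.evaluate_model(
                        spec, X, y, scheme, engine=engine
                    )
                    null, p = evaluation.permutation_test(
                        spec, X, y, scheme,
                        n_perm=n_perm,
                        perm_splits=perm_splits[algorithm],
                        perm_seed=perm_seed,
                        plus_one=plus_one,
                        lambda_grid=self.lambda_grid,
                    )
                    res.null_rmeans = null
                    res.p = p
                    nulls.append(null)
                else:
                    res = evaluation.evaluate_model(
                        spec, X, y, scheme, lambda_grid=self.lambda_grid
                    )
                cell_results.append(res)
            if n_perm > 0 and cell_results:
                null_matrix = np.column_stack(nulls)
                observed = np.array([r.r_mean for r in cell_results])
                p_fwe = evaluation.westfall_young(
                    null_matrix, observed, plus_one=plus_one
                )
                for res, pf in zip(cell_results, p_fwe):
                    res.p_fwe = float(pf)
            all_results.extend(cell_results)
        return StudyResults(results=all_results, scheme=scheme, n_perm=n_perm)


def run_study(
    cohort: simulate.SyntheticCohort | str | Path,
    algorithms: tuple[str, ...] = ALGORITHMS,
    scheme: SplitScheme = SplitScheme(),
    n_perm: int = 0,
    perm_seed: int = 0,
    bank_seed: int = 0,
    output_dir: str | Path | None = None,
    make_plots: bool = False,
) -> StudyResults:
    """End-to-end study on a cohort (object or exported directory).

    Trains the synthetic default proxy bank when meta-matching is requested,
    fits the grid, and optionally writes the results tables (and per-split
    figures) to ``output_dir``.
    """
    if not isinstance(cohort, simulate.SyntheticCohort):
        cohort = simulate.load_cohort(cohort)
    study = PredictionStudy.from_cohort(cohort)
    if METAMATCH in algorithms:
        study.with_default_bank(cohort.config.n_regions, seed=bank_seed)
    results = study.fit(
        algorithms=algorithms, scheme=scheme, n_perm=n_perm, perm_seed=perm_seed
    )
    if output_dir is not None:
        results.save(output_dir)
        if make_plots:
            results.plot_split_distributions(
                Path(output_dir) / "split_distributions.png"
            )
    return results
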