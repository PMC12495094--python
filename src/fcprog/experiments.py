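"""Predefined validation experiments at desk scale.

These runners compute the package's headline methodological checks from
scratch on seeded synthetic cohorts: oracle equivalence of the core
estimators against independent brute-force solutions, calibration of the
permutation p-value under the null, familywise-error control of the
Westfall-Young correction, recovery of planted prognostic signal, and the
transfer-benefit property of proxy-feature stacking.

Study conditions (cohort size 48, effect size 0.5 where a signal is
planted, 20 regions, 60 time points, 5 causal edges, 99 permutations of 10
splits) are the package's desk-scale defaults: large enough for the
properties to be decidable, small enough to run on one CPU in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import cpm, evaluation, krr, metamatch, simulate
from .evaluation import ModelSpec, SplitScheme

NULL_COHORT = dict(
    n_subjects=48, n_regions=20, n_timepoints=60,
    effect_r2=0.0, n_causal_edges=5, attrition_fraction=0.0,
)
SIGNAL_COHORT = dict(
    n_subjects=48, n_regions=20, n_timepoints=60,
    effect_r2=0.5, n_causal_edges=5, attrition_fraction=0.0,
)


def cpm_selection_brute_force(
    X: np.ndarray, y: np.ndarray, sign: str, alpha: float
) -> set[int]:
    """Independent per-edge oracle: loop, pearsonr, explicit p threshold."""
    selected = set()
    for e in range(X.shape[1]):
        if np.ptp(X[:, e]) == 0:
            continue
        r, p = stats.pearsonr(X[:, e], y)
        if p < alpha and ((sign == "positive" and r > 0) or (sign == "negative" and r < 0)):
            selected.add(e)
    return selected


def cpm_selection_oracle_agreement(
    n_instances: int = 20, seed: int = 0, n: int = 10, n_edges: int = 20
) -> float:
    """Fraction of seeded random instances where vectorized CPM selection
    equals the brute-force per-edge loop exactly (both signs)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        X = rng.standard_normal((n, n_edges))
        y = rng.standard_normal(n)
        ok = True
        for sign in ("positive", "negative"):
            fast = set(cpm.select_features(X, y, sign, 0.05).tolist())
            ok &= fast == cpm_selection_brute_force(X, y, sign, 0.05)
        agree += ok
    return agree / n_instances


def krr_solver_max_error(
    n_instances: int = 20, seed: int = 0, n: int = 12, n_edges: int = 30
) -> float:
    """Max abs deviation of KRR predictions from an independent dense solve.

    For each seeded instance and a fixed lambda, compares the package's
    eigendecomposition route against
    ``K_test (K + lambda I)^{-1} (y - y_bar) + y_bar`` computed with a plain
    dense solver.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        X = rng.standard_normal((n, n_edges))
        X_test = rng.standard_normal((4, n_edges))
        y = rng.standard_normal(n)
        lam = float(10.0 ** rng.uniform(-2, 1))
        model = krr.fit(X, y, lambda_grid=np.array([lam]), seed=i)
        pred = krr.predict(model, X_test)
        K = krr.build_kernel(X, X)
        k_te = krr.build_kernel(X_test, X)
        ref = k_te @ np.linalg.solve(
            K + lam * np.eye(n), y - y.mean()
        ) + y.mean()
        worst = max(worst, float(np.max(np.abs(pred - ref))))
    return worst


@dataclass
class NullCalibration:
    """Null-cohort permutation calibration over an 8-model CPM grid."""

    p_values: np.ndarray          # focal-model p per cohort
    type1_error: float            # fraction of focal p < .05
    ks_statistic: float
    ks_pvalue: float
    fwe_rate: float               # cohorts where any of 8 models has p_fwe < .05
    monotone_violations: int      # cells with p_fwe < p (must be 0)
    n_cohorts: int


def null_calibration(
    n_cohorts: int = 200,
    n_perm: int = 99,
    n_splits: int = 10,
    seed: int = 0,
) -> NullCalibration:
    """Permutation p uniformity and Westfall-Young FWE control under the null.

    Each seeded null cohort (no planted effect) is pushed through the
    8-model baseline-FC CPM grid with ``n_perm`` permutations of
    ``n_splits`` splits; the focal model's p-value is collected for the
    uniformity and type-I checks, and the grid's familywise rejection for
    the FWE check.
    """
    specs = [
        s for s in evaluation.enumerate_models(evaluation.CPM)
        if s.predictor == "baseline_fc"
    ]
    focal = specs[0]
    p_focal = np.empty(n_cohorts)
    fwe_hits = 0
    violations = 0
    scheme = None
    for c in range(n_cohorts):
        cfg = simulate.CohortConfig(seed=seed + c, **NULL_COHORT)
        cohort = simulate.generate_cohort(cfg)
        X, _ = cohort.baseline_fc_vectors()
        scheme = SplitScheme(n_splits=n_splits, base_seed=seed + c)
        observed, nulls, ps = [], [], []
        for spec in specs:
            y = cohort.targets[
                ("SOFAS" if spec.measure == "functioning" else "BPRS",
                 spec.timepoint)
            ]
            null, p = evaluation.permutation_test(
                spec, X, y, scheme,
                n_perm=n_perm, perm_splits=n_splits,
                # distinct stream from the cohort-generation seed: the
                # permutation indices must be independent of the data
                perm_seed=1_000_000_000 + seed + c,
            )
            res = evaluation.evaluate_model(spec, X, y, scheme)
            observed.append(res.r_mean)
            nulls.append(null)
            ps.append(p)
            if spec == focal:
                p_focal[c] = p
        p_fwe = evaluation.westfall_young(
            np.column_stack(nulls), np.array(observed)
        )
        violations += int(np.sum(p_fwe < np.array(ps)))
        fwe_hits += int(np.any(p_fwe < 0.05))
    ks_stat, ks_p = stats.kstest(p_focal, "uniform")
    return NullCalibration(
        p_values=p_focal,
        type1_error=float(np.mean(p_focal < 0.05)),
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        fwe_rate=fwe_hits / n_cohorts,
        monotone_violations=violations,
        n_cohorts=n_cohorts,
    )


@dataclass
class SignalRecovery:
    """Planted-effect recovery at effect_r2 = 0.5, n = 48."""

    cpm_rmeans: np.ndarray
    krr_rmeans: np.ndarray
    cpm_rejection_rate: float
    krr_rejection_rate: float
    edge_recovery: np.ndarray     # per-cohort fraction of causal edges found
    n_cohorts: int

    @property
    def cpm_mean_rmean(self) -> float:
        return float(self.cpm_rmeans.mean())

    @property
    def krr_mean_rmean(self) -> float:
        return float(self.krr_rmeans.mean())

    @property
    def mean_edge_recovery(self) -> float:
        return float(self.edge_recovery.mean())


def signal_recovery(
    n_cohorts: int = 50,
    n_perm: int = 99,
    n_splits: int = 10,
    seed: int = 0,
) -> SignalRecovery:
    """CPM and KRR performance and causal-edge recovery on planted cohorts.

    The functioning/6-month cell is evaluated (the planted latent loads
    positively on functioning, so CPM uses the positive-feature model);
    edge recovery is the fraction of planted causal edges present in the
    union of positive and negative whole-cohort selections at alpha = .05.
    """
    spec_cpm = ModelSpec(
        evaluation.CPM, "functioning", 6, "baseline_fc", sign="positive"
    )
    spec_krr = ModelSpec(evaluation.KRR, "functioning", 6, "baseline_fc")
    r_cpm = np.empty(n_cohorts)
    r_krr = np.empty(n_cohorts)
    rej_cpm = np.zeros(n_cohorts, dtype=bool)
    rej_krr = np.zeros(n_cohorts, dtype=bool)
    recovery = np.empty(n_cohorts)
    for c in range(n_cohorts):
        cfg = simulate.CohortConfig(seed=seed + c, **SIGNAL_COHORT)
        cohort = simulate.generate_cohort(cfg)
        X, _ = cohort.baseline_fc_vectors()
        y = cohort.targets[("SOFAS", 6)]
        scheme = SplitScheme(n_splits=n_splits, base_seed=seed + c)
        for spec, r_arr, rej_arr in (
            (spec_cpm, r_cpm, rej_cpm),
            (spec_krr, r_krr, rej_krr),
        ):
            res = evaluation.evaluate_model(spec, X, y, scheme)
            _, p = evaluation.permutation_test(
                spec, X, y, scheme,
                n_perm=n_perm, perm_splits=n_splits,
                perm_seed=1_000_000_000 + seed + c,
            )
            r_arr[c] = res.r_mean
            rej_arr[c] = p < 0.05
        found = set(cpm.select_features(X, y, "positive", 0.05).tolist()) | set(
            cpm.select_features(X, y, "negative", 0.05).tolist()
        )
        causal = set(cohort.causal_edges.tolist())
        recovery[c] = len(found & causal) / len(causal)
    return SignalRecovery(
        cpm_rmeans=r_cpm,
        krr_rmeans=r_krr,
        cpm_rejection_rate=float(rej_cpm.mean()),
        krr_rejection_rate=float(rej_krr.mean()),
        edge_recovery=recovery,
        n_cohorts=n_cohorts,
    )


@dataclass
class TransferBenefit:
    """Meta-matching vs raw-FC KRR at target n = 40."""

    mm_rmeans: np.ndarray
    raw_rmeans: np.ndarray
    n_seeds: int

    @property
    def mean_gain(self) -> float:
        return float((self.mm_rmeans - self.raw_rmeans).mean())


def transfer_benefit(
    correlated: bool,
    n_seeds: int = 50,
    seed: int = 0,
    n_regions: int = 20,
    n_target: int = 40,
    n_source: int = 2000,
    target_r2: float = 0.65,
    n_splits: int = 10,
) -> TransferBenefit:
    """Proxy-stacking vs raw-FC KRR on targets tied to (or free of) a
    source phenotype.

    When ``correlated``, the target shares the first base phenotype's dense
    FC readout (correlation ~ sqrt(target_r2) with the construct, ~ 0.7 with
    the noisy phenotype); otherwise the target uses an independent random
    readout.  Source and target cohorts share the population structure
    (many-mode between-subject variation), which is what makes a
    source-trained readout transferable.
    """
    spec = ModelSpec(evaluation.KRR, "functioning", 6, "baseline_fc")
    mm = np.empty(n_seeds)
    raw = np.empty(n_seeds)
    for i in range(n_seeds):
        s0 = seed + i
        structure_seed = 700_000 + s0
        rng = np.random.default_rng(s0)
        cohorts, weights = metamatch.simulate_source_cohorts(
            n_regions=n_regions, n_subjects=n_source,
            seed=s0, structure_seed=structure_seed,
        )
        bank = metamatch.train_bank(cohorts, seed=s0)
        X = simulate.generate_fc_features(
            n_target, n_regions, 60, seed=900_000 + s0,
            n_subject_modes=15, mode_strength=0.25,
            structure_seed=structure_seed,
        )
        if correlated:
            w = weights["base_phen_000"]
        else:
            w = rng.standard_normal(X.shape[1])
        sgn = X @ w
        sgn = (sgn - sgn.mean()) / sgn.std()
        y = np.sqrt(target_r2) * sgn + np.sqrt(
            1 - target_r2
        ) * rng.standard_normal(n_target)
        proxies = metamatch.generate_proxies(bank, X).values
        proxies = proxies[:, np.ptp(proxies, axis=0) > 0]
        scheme = SplitScheme(n_splits=n_splits, base_seed=s0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm[i] = evaluation.evaluate_model(spec, proxies, y, scheme).r_mean
            raw[i] = evaluation.evaluate_model(spec, X, y, scheme).r_mean
    return TransferBenefit(mm_rmeans=mm, raw_rmeans=raw, n_seeds=n_seeds)
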