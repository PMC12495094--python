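"""Model grid, repeated-split scoring, permutation and familywise inference."""

import numpy as np
import pytest

import fcprog
from fcprog import evaluation, cpm
from fcprog._utils import columnwise_pearson, fold_allocation
from fcprog.evaluation import ModelSpec, SplitScheme


class TestEnumerateModels:
    @pytest.mark.parametrize(
        "algorithm,count", [("cpm", 16), ("krr", 8), ("metamatch", 4)]
    )
    def test_factorial_counts(self, algorithm, count):
        assert len(evaluation.enumerate_models(algorithm)) == count

    def test_sign_only_for_cpm(self):
        for spec in evaluation.enumerate_models("cpm"):
            assert spec.sign in ("positive", "negative")
        for algorithm in ("krr", "metamatch"):
            for spec in evaluation.enumerate_models(algorithm):
                assert spec.sign is None

    def test_metamatch_is_baseline_only(self):
        for spec in evaluation.enumerate_models("metamatch"):
            assert spec.predictor == "baseline_fc"

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            evaluation.enumerate_models("svm")

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            ModelSpec("krr", "symptoms", 6, "baseline_fc", sign="positive")
        with pytest.raises(ValueError, match="sign"):
            ModelSpec("cpm", "symptoms", 6, "baseline_fc")
        with pytest.raises(ValueError, match="baseline"):
            ModelSpec("metamatch", "symptoms", 6, "delta_fc")


class TestRunSplit:
    def test_pooled_correlation_matches_hand_computation(self, monkeypatch, rng):
        # mock predictor: fixed out-of-fold predictions, hand-computed r
        n = 8
        y = rng.standard_normal(n)
        preds = rng.standard_normal(n)
        monkeypatch.setattr(
            evaluation.Engine, "predictions",
            lambda self, Y, fold_ids, r: preds[:, None],
        )
        spec = ModelSpec("krr", "functioning", 6, "baseline_fc")
        r = evaluation.run_split(spec, rng.standard_normal((n, 6)), y, np.resize(np.arange(4), n))
        assert r == pytest.approx(np.corrcoef(preds, y)[0, 1], abs=1e-12)

    def test_perfect_and_antiperfect_predictions(self, monkeypatch, rng):
        n = 8
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, 6))
        folds = np.resize(np.arange(4), n)
        spec = ModelSpec("krr", "functioning", 6, "baseline_fc")
        monkeypatch.setattr(
            evaluation.Engine, "predictions", lambda self, Y, f, r: y[:, None]
        )
        assert evaluation.run_split(spec, X, y, folds) == pytest.approx(1.0)
        monkeypatch.setattr(
            evaluation.Engine, "predictions", lambda self, Y, f, r: -y[:, None]
        )
        assert evaluation.run_split(spec, X, y, folds) == pytest.approx(-1.0)

    def test_constant_predictions_warn_and_score_zero(self, monkeypatch, rng):
        n = 12
        X = rng.standard_normal((n, 10))
        y = rng.standard_normal(n)
        spec = ModelSpec("cpm", "functioning", 6, "baseline_fc", sign="positive")
        monkeypatch.setattr(
            evaluation.Engine, "predictions",
            lambda self, Y, f, r: np.full((n, 1), 0.37),
        )
        with pytest.warns(UserWarning, match="constant pooled"):
            r = evaluation.run_split(spec, X, y, np.resize(np.arange(4), n))
        assert r == 0.0


class TestEvaluateModel:
    def test_single_split_equals_run_split(self, rng):
        n = 16
        X = rng.standard_normal((n, 20))
        y = X[:, 0] + rng.standard_normal(n)
        spec = ModelSpec("cpm", "functioning", 6, "baseline_fc", sign="positive")
        scheme = SplitScheme(n_splits=1, base_seed=5)
        res = evaluation.evaluate_model(spec, X, y, scheme)
        fold_ids = fold_allocation(n, 4, np.random.default_rng([5, 0]))
        assert res.r_mean == pytest.approx(
            evaluation.run_split(spec, X, y, fold_ids), abs=1e-12
        )

    def test_r_mean_is_mean_of_split_correlations(self, rng):
        n = 16
        X = rng.standard_normal((n, 20))
        y = X[:, 1] + rng.standard_normal(n)
        spec = ModelSpec("krr", "functioning", 6, "baseline_fc")
        res = evaluation.evaluate_model(
            spec, X, y, SplitScheme(n_splits=4, base_seed=0)
        )
        assert res.r_per_split.size == 4
        assert res.r_mean == pytest.approx(res.r_per_split.mean())
        assert np.all(np.abs(res.r_per_split) <= 1.0)

    def test_deterministic_given_scheme(self, rng):
        n = 16
        X = rng.standard_normal((n, 20))
        y = rng.standard_normal(n)
        spec = ModelSpec("cpm", "symptoms", 12, "delta_fc", sign="negative")
        scheme = SplitScheme(n_splits=3, base_seed=9)
        r1 = evaluation.evaluate_model(spec, X, y, scheme).r_per_split
        r2 = evaluation.evaluate_model(spec, X, y, scheme).r_per_split
        assert np.array_equal(r1, r2)


class TestPermutationTest:
    def test_p_value_tie_convention_hand_count(self):
        null = np.array([[0.1], [0.2], [0.3], [0.4]])
        assert evaluation.westfall_young(null, np.array([0.25]))[0] == 0.5

    def test_boundary_p_values(self):
        null = np.array([[0.1], [0.2], [0.3], [0.4]])
        assert evaluation.westfall_young(null, np.array([0.5]))[0] == 0.0
        assert evaluation.westfall_young(null, np.array([0.05]))[0] == 1.0

    def test_plus_one_estimator_never_zero(self):
        null = np.array([[0.1], [0.2]])
        p = evaluation.westfall_young(null, np.array([0.9]), plus_one=True)
        assert p[0] == pytest.approx(1 / 3)

    def test_null_distribution_and_p_on_noise(self, rng):
        n = 16
        X = rng.standard_normal((n, 15))
        y = rng.standard_normal(n)
        spec = ModelSpec("cpm", "functioning", 6, "baseline_fc", sign="positive")
        scheme = SplitScheme(n_splits=3, base_seed=2)
        null, p = evaluation.permutation_test(
            spec, X, y, scheme, n_perm=40, perm_splits=3, perm_seed=8
        )
        assert null.shape == (40,)
        obs = evaluation.evaluate_model(spec, X, y, scheme).r_mean
        assert p == pytest.approx(np.mean(null >= obs))

    def test_invalid_n_perm(self, rng):
        spec = ModelSpec("krr", "functioning", 6, "baseline_fc")
        with pytest.raises(ValueError, match="n_perm"):
            evaluation.permutation_test(
                spec, rng.standard_normal((10, 5)), rng.standard_normal(10),
                SplitScheme(n_splits=1), n_perm=0,
            )

    def test_reproducible_given_seeds(self, rng):
        n = 16
        X = rng.standard_normal((n, 15))
        y = rng.standard_normal(n)
        spec = ModelSpec("krr", "functioning", 6, "baseline_fc")
        scheme = SplitScheme(n_splits=2, base_seed=3)
        n1, p1 = evaluation.permutation_test(
            spec, X, y, scheme, n_perm=10, perm_splits=2, perm_seed=4
        )
        n2, p2 = evaluation.permutation_test(
            spec, X, y, scheme, n_perm=10, perm_splits=2, perm_seed=4
        )
        assert np.array_equal(n1, n2) and p1 == p2


class TestWestfallYoung:
    def test_hand_enumerated_two_model_example(self):
        null = np.array(
            [[0.10, 0.20], [0.30, 0.05], [0.20, 0.25], [0.05, 0.15]]
        )
        observed = np.array([0.22, 0.10])
        # row maxima: .20 .30 .25 .15 -> p_fwe(.22)=2/4, p_fwe(.10)=4/4
        p_fwe = evaluation.westfall_young(null, observed)
        assert np.allclose(p_fwe, [0.5, 1.0])

    def test_fwe_dominates_per_model_p(self, rng):
        null = rng.standard_normal((50, 6)) * 0.1
        observed = rng.standard_normal(6) * 0.1
        p_fwe = evaluation.westfall_young(null, observed)
        for m in range(6):
            p_m = np.mean(null[:, m] >= observed[m])
            assert p_fwe[m] >= p_m

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            evaluation.westfall_young(rng.standard_normal((10, 3)), np.zeros(4))


class TestLeakageGuard:
    def test_full_sample_feature_selection_inflates_null_performance(self):
        # mutant pipeline: select edges on ALL subjects, then cross-validate
        # only the line fit.  On pure-noise data this must inflate apparent
        # performance, demonstrating that in-fold selection is load-bearing.
        proper_means, leaky_means = [], []
        for seed in (77, 78, 79, 80, 81):
            cfg = fcprog.CohortConfig(
                n_subjects=48, n_regions=20, n_timepoints=60,
                effect_r2=0.0, attrition_fraction=0.0, seed=seed,
            )
            cohort = fcprog.generate_cohort(cfg)
            X, _ = cohort.baseline_fc_vectors()
            y = cohort.targets[("SOFAS", 6)]
            spec = ModelSpec(
                "cpm", "functioning", 6, "baseline_fc", sign="positive"
            )
            scheme = SplitScheme(n_splits=10, base_seed=0)
            proper_means.append(
                evaluation.evaluate_model(spec, X, y, scheme).r_mean
            )

            leaked_edges = cpm.select_features(X, y, "positive", 0.05)
            scores = np.asarray(cpm.summary_score(X, leaked_edges))[:, None]
            leaky_r = []
            for s in range(scheme.n_splits):
                fold_ids = fold_allocation(
                    48, 4, np.random.default_rng([scheme.base_seed, s])
                )
                preds = np.empty(48)
                for f in range(4):
                    te = fold_ids == f
                    model = cpm.fit(scores[~te], y[~te], "positive", alpha=1.0)
                    preds[te] = cpm.predict(model, scores[te])
                leaky_r.append(np.corrcoef(preds, y)[0, 1])
            leaky_means.append(float(np.mean(leaky_r)))
        proper = float(np.mean(proper_means))
        leaky = float(np.mean(leaky_means))
        assert leaky > proper + 0.2
        assert abs(proper) < 0.15


def test_columnwise_pearson_degenerate_columns_score_zero(rng):
    A = np.column_stack([np.ones(10), rng.standard_normal(10)])
    B = rng.standard_normal((10, 2))
    r = columnwise_pearson(A, B)
    assert r[0] == 0.0
    assert abs(r[1]) <= 1.0
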