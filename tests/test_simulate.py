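"""Synthetic cohort generation: determinism, calibration, export round trip."""

import numpy as np
import pytest

import fcprog
from fcprog import connectome, outcomes, simulate


def _cfg(**kw):
    base = dict(
        n_subjects=12, n_regions=8, n_timepoints=30,
        effect_r2=0.4, n_causal_edges=3, attrition_fraction=0.25, seed=5,
    )
    base.update(kw)
    return fcprog.CohortConfig(**base)


class TestConfigValidation:
    def test_effect_without_causal_edges_rejected(self):
        with pytest.raises(ValueError, match="causal edge"):
            _cfg(effect_r2=0.3, n_causal_edges=0)

    @pytest.mark.parametrize(
        "kw", [dict(effect_r2=1.2), dict(attrition_fraction=-0.1),
               dict(arm_fraction=2.0), dict(n_timepoints=2),
               dict(n_causal_edges=10**6)],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestGenerateCohort:
    def test_seeded_reproducibility(self):
        a = fcprog.generate_cohort(_cfg())
        b = fcprog.generate_cohort(_cfg())
        for sa, sb in zip(a.baseline_series, b.baseline_series):
            assert np.array_equal(sa, sb)
        assert np.array_equal(a.edge_weights, b.edge_weights)
        assert a.outcome_table.scores.equals(b.outcome_table.scores)
        assert a.arms == b.arms

    def test_attrition_count(self):
        cohort = fcprog.generate_cohort(
            _cfg(n_subjects=50, attrition_fraction=0.3)
        )
        assert int(cohort.has_followup().sum()) == 35

    def test_ground_truth_weight_sparsity(self, small_cohort):
        w = small_cohort.edge_weights
        assert np.count_nonzero(w) == small_cohort.config.n_causal_edges

    def test_planted_target_matches_outcome_table_exactly(self, small_cohort):
        targets = outcomes.build_targets(
            small_cohort.outcome_table, "functioning", 6
        )
        expected = small_cohort.targets[("SOFAS", 6)]
        for i, sid in enumerate(small_cohort.subject_ids):
            assert targets[sid] == pytest.approx(expected[i], abs=1e-12)

    def test_scores_respect_scale_bounds(self, small_cohort):
        scores = small_cohort.outcome_table.scores
        sofas = scores[scores["scale"] == "SOFAS"]["score"]
        bprs = scores[scores["scale"] == "BPRS"]["score"]
        assert sofas.between(0, 100).all()
        assert bprs.between(24, 168).all()

    def test_item_scores_sum_to_totals(self, small_cohort):
        table = small_cohort.outcome_table
        items = table.items.set_index(["subject_id", "visit_month"])
        totals = table.scores[table.scores["scale"] == "BPRS"]
        for _, row in totals.iterrows():
            item_sum = items.loc[(row["subject_id"], row["visit_month"])][
                list(outcomes.BPRS_ITEMS)
            ].sum()
            assert item_sum == pytest.approx(row["score"], abs=1e-9)

    def test_null_effect_targets_uncorrelated_with_planted_signal(self):
        # Monte Carlo over seeded null cohorts: the correlation between the
        # generated target and the noiseless predictor w.x should stay within
        # the two-sided 95% null band for that n in ~95% of cohorts.
        n, inside = 20, 0
        n_cohorts = 200
        bound = 1.96 / np.sqrt(n - 1)
        for seed in range(n_cohorts):
            cohort = fcprog.generate_cohort(
                _cfg(n_subjects=n, effect_r2=0.0, attrition_fraction=0.0,
                     seed=1000 + seed)
            )
            s = cohort.latent_signal
            t = cohort.targets[("SOFAS", 6)]
            r = np.corrcoef(s, t)[0, 1]
            inside += abs(r) < bound
        assert inside / n_cohorts > 0.90

    def test_effect_size_calibration(self):
        # mean squared correlation between target and noiseless predictor
        # approximately equals effect_r2 over many seeded cohorts
        rho2 = 0.4
        r2 = []
        for seed in range(60):
            cohort = fcprog.generate_cohort(
                _cfg(n_subjects=40, effect_r2=rho2, attrition_fraction=0.0,
                     seed=2000 + seed)
            )
            r = np.corrcoef(
                cohort.latent_signal, cohort.targets[("SOFAS", 6)]
            )[0, 1]
            r2.append(r**2)
        assert np.mean(r2) == pytest.approx(rho2, abs=0.05)

    def test_symptom_scale_loads_negatively_on_shared_latent(self):
        cohort = fcprog.generate_cohort(
            _cfg(n_subjects=40, effect_r2=0.6, attrition_fraction=0.0)
        )
        r = np.corrcoef(
            cohort.latent_signal, cohort.targets[("BPRS", 6)]
        )[0, 1]
        assert r < 0


class TestExport:
    def test_file_counts_three_subjects_one_attrition(self, tmp_path):
        cohort = fcprog.generate_cohort(
            _cfg(n_subjects=3, attrition_fraction=1 / 3)
        )
        out = simulate.export_cohort(cohort, tmp_path / "cohort")
        ts_files = list(out.glob("*_timeseries.tsv"))
        assert len(ts_files) == 5
        assert (out / "outcomes.csv").exists()

    def test_refuses_existing_directory_unless_forced(self, tmp_path):
        cohort = fcprog.generate_cohort(_cfg(n_subjects=3))
        out = tmp_path / "cohort"
        simulate.export_cohort(cohort, out)
        with pytest.raises(FileExistsError):
            simulate.export_cohort(cohort, out)
        simulate.export_cohort(cohort, out, force=True)

    def test_round_trip_fc_identical_to_full_precision(self, tmp_path, small_cohort):
        out = simulate.export_cohort(small_cohort, tmp_path / "cohort")
        back = simulate.load_cohort(out)
        X1, _ = small_cohort.baseline_fc_vectors()
        X2, _ = back.baseline_fc_vectors()
        assert np.array_equal(X1, X2)
        D1, _ = small_cohort.delta_fc_vectors()
        D2, _ = back.delta_fc_vectors()
        assert np.array_equal(D1, D2)

    def test_outcome_table_schema(self, tmp_path, small_cohort):
        out = simulate.export_cohort(small_cohort, tmp_path / "cohort")
        table = outcomes.OutcomeTable.from_csv(
            out / "outcomes.csv", out / "bprs_items.csv"
        )
        assert set(table.scores["scale"]) == {"SOFAS", "BPRS"}
        assert set(table.scores["visit_month"]) == {0, 6, 12}
        assert set(table.scores["arm"]) <= {"placebo", "medication"}

    def test_export_byte_identical_for_same_config(self, tmp_path):
        cohort1 = fcprog.generate_cohort(_cfg(n_subjects=4))
        cohort2 = fcprog.generate_cohort(_cfg(n_subjects=4))
        d1 = simulate.export_cohort(cohort1, tmp_path / "a")
        d2 = simulate.export_cohort(cohort2, tmp_path / "b")
        for f1 in sorted(d1.iterdir()):
            f2 = d2 / f1.name
            assert f2.read_bytes() == f1.read_bytes()


def test_generate_fc_features_shapes_and_determinism():
    X1 = simulate.generate_fc_features(6, 8, 30, seed=3)
    X2 = simulate.generate_fc_features(6, 8, 30, seed=3)
    assert X1.shape == (6, connectome.edge_count(8))
    assert np.array_equal(X1, X2)
    # shared structure seed, different subjects
    Xa = simulate.generate_fc_features(6, 8, 30, seed=4, structure_seed=9)
    Xb = simulate.generate_fc_features(6, 8, 30, seed=5, structure_seed=9)
    assert not np.array_equal(Xa, Xb)
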