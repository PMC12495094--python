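"""Clinical outcome targets: proportional change, slopes, subscale sums."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcprog import outcomes


class TestProportionalChange:
    def test_basic_arithmetic(self):
        assert outcomes.proportional_change(50, 60) == pytest.approx(0.20)

    @pytest.mark.parametrize("y", [1.0, 37.5, 100.0, -4.0])
    def test_no_change_is_zero(self, y):
        assert outcomes.proportional_change(y, y) == 0.0

    def test_group_mean_symptom_decline(self):
        # change of the group means 57.8 -> 42.6 (not the mean of
        # per-patient changes, which is a different quantity)
        assert outcomes.proportional_change(57.8, 42.6) == pytest.approx(
            -0.26297577, abs=1e-8
        )

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            outcomes.proportional_change(0, 10)

    @settings(deadline=None, max_examples=50)
    @given(
        y1=st.floats(1.0, 100.0),
        y2=st.floats(0.0, 200.0),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_invariance(self, y1, y2, c):
        a = outcomes.proportional_change(y1, y2)
        b = outcomes.proportional_change(c * y1, c * y2)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestSlopeOutcome:
    def test_exact_line(self):
        assert outcomes.slope_outcome([0, 6, 12], [50, 60, 70]) == pytest.approx(5 / 3)

    def test_constant_scores_give_zero(self):
        assert outcomes.slope_outcome([0, 6, 12], [42, 42, 42]) == 0.0

    def test_matches_closed_form_on_noncollinear_points(self, rng):
        t = np.array([0.0, 6.0, 12.0])
        y = rng.normal(size=3) * 10 + 50
        tc = t - t.mean()
        expected = np.sum(tc * (y - y.mean())) / np.sum(tc**2)
        assert outcomes.slope_outcome(t, y) == pytest.approx(expected, abs=1e-12)

    def test_two_points_allowed_missing_visit(self):
        assert outcomes.slope_outcome([0, 12], [50, 62]) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            outcomes.slope_outcome([6], [50])
        with pytest.raises(ValueError):
            outcomes.slope_outcome([6, 6], [50, 60])


class TestPositiveSymptomScore:
    def _items(self, value):
        return {name: value for name in outcomes.BPRS_ITEMS}

    def test_floor_and_ceiling(self):
        assert outcomes.positive_symptom_score(self._items(1)) == 4
        assert outcomes.positive_symptom_score(self._items(7)) == 28

    def test_sums_exactly_the_four_named_items(self):
        items = self._items(1)
        for name, v in zip(outcomes.POSITIVE_SYMPTOM_ITEMS, (3, 2, 5, 1)):
            items[name] = v
        assert outcomes.positive_symptom_score(items) == 11

    def test_missing_item_rejected(self):
        items = self._items(3)
        del items["grandiosity"]
        with pytest.raises(ValueError, match="grandiosity"):
            outcomes.positive_symptom_score(items)


def _table(rows):
    return outcomes.OutcomeTable(
        scores=pd.DataFrame(
            rows, columns=["subject_id", "arm", "scale", "visit_month", "score"]
        )
    )


class TestBuildTargets:
    def test_proportional_change_composition(self):
        t = _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s1", "placebo", "SOFAS", 6, 60.0),
            ]
        )
        targets = outcomes.build_targets(t, "functioning", 6)
        assert targets["s1"] == pytest.approx(0.20)

    def test_subject_missing_required_visit_excluded(self):
        t = _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s1", "placebo", "SOFAS", 12, 55.0),
                ("s2", "placebo", "SOFAS", 0, 40.0),
            ]
        )
        targets = outcomes.build_targets(t, "functioning", 12)
        assert list(targets.index) == ["s1"]

    def test_complete_cohort_fully_retained(self):
        rows = []
        for sid in ("a", "b", "c"):
            for m in (0, 6, 12):
                rows.append((sid, "medication", "BPRS", m, 60.0 - m))
        targets = outcomes.build_targets(_table(rows), "symptoms", 6)
        assert len(targets) == 3

    def test_never_imputes_output_not_larger_than_input(self):
        t = _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s2", "placebo", "SOFAS", 6, 60.0),
            ]
        )
        with pytest.raises(ValueError, match="no subject"):
            outcomes.build_targets(t, "functioning", 6)

    def test_slope_uses_available_visits(self):
        t = _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s1", "placebo", "SOFAS", 6, 56.0),
                ("s1", "placebo", "SOFAS", 12, 62.0),
                ("s2", "placebo", "SOFAS", 0, 50.0),
                ("s2", "placebo", "SOFAS", 12, 56.0),
            ]
        )
        targets = outcomes.build_targets(t, "functioning", 12, outcomes.SLOPE)
        assert targets["s1"] == pytest.approx(1.0)
        assert targets["s2"] == pytest.approx(0.5)

    def test_positive_change_from_item_scores(self):
        scores = pd.DataFrame(
            [
                ("s1", "placebo", "BPRS", 0, 48.0),
                ("s1", "placebo", "BPRS", 6, 40.0),
            ],
            columns=["subject_id", "arm", "scale", "visit_month", "score"],
        )
        base = {name: 2.0 for name in outcomes.BPRS_ITEMS}
        follow = dict(base)
        for name in outcomes.POSITIVE_SYMPTOM_ITEMS:
            base[name] = 4.0   # subscale 16 at baseline
            follow[name] = 2.0  # subscale 8 at follow-up
        items = pd.DataFrame(
            [
                {"subject_id": "s1", "visit_month": 0, **base},
                {"subject_id": "s1", "visit_month": 6, **follow},
            ]
        )
        t = outcomes.OutcomeTable(scores=scores, items=items)
        targets = outcomes.build_targets(
            t, "symptoms", 6, outcomes.POSITIVE_CHANGE
        )
        assert targets["s1"] == pytest.approx((8 - 16) / 16)

    def test_arm_filter_restricts_subjects(self):
        t = _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s1", "placebo", "SOFAS", 6, 60.0),
                ("s2", "medication", "SOFAS", 0, 50.0),
                ("s2", "medication", "SOFAS", 6, 40.0),
            ]
        )
        targets = outcomes.build_targets(
            t.filter_arm("placebo"), "functioning", 6
        )
        assert list(targets.index) == ["s1"]


def test_table_validation_rejects_out_of_range_and_duplicates():
    with pytest.raises(ValueError, match="SOFAS"):
        _table([("s1", "placebo", "SOFAS", 0, 104.0)])
    with pytest.raises(ValueError, match="one score"):
        _table(
            [
                ("s1", "placebo", "SOFAS", 0, 50.0),
                ("s1", "placebo", "SOFAS", 0, 51.0),
            ]
        )
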