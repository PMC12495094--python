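"""Clinical outcome targets derived from longitudinal scale scores.

Two bounded instruments are supported: a 0-100 social/occupational
functioning scale (SOFAS-like, higher is better) and a 24-item psychiatric
symptom scale with 7-point items (BPRS-like, total 24-168, higher is worse).
The primary prognostic target is the proportional change score
``(y2 - y1) / y1`` between baseline and a later visit; exploratory targets
are the least-squares slope of scores over all available visits and the
proportional change of a 4-item positive-symptom subscale.

Subjects with missing required visits are dropped, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOFAS = "SOFAS"
BPRS = "BPRS"
FUNCTIONING = "functioning"
SYMPTOMS = "symptoms"
MEASURE_TO_SCALE = {FUNCTIONING: SOFAS, SYMPTOMS: BPRS}

PLACEBO = "placebo"
MEDICATION = "medication"

VISIT_MONTHS = (0, 6, 12)

SOFAS_RANGE = (0.0, 100.0)
BPRS_TOTAL_RANGE = (24.0, 168.0)
BPRS_ITEM_RANGE = (1.0, 7.0)

# 24-item symptom inventory; the four positive-symptom items are named as
# in the expanded BPRS, the rest follow the standard item list.
BPRS_ITEMS = (
    "somatic_concern",
    "anxiety",
    "depression",
    "suicidality",
    "guilt",
    "hostility",
    "elevated_mood",
    "grandiosity",
    "suspiciousness",
    "hallucinatory_behavior",
    "unusual_thought_content",
    "bizarre_behavior",
    "self_neglect",
    "disorientation",
    "conceptual_disorganization",
    "blunted_affect",
    "emotional_withdrawal",
    "motor_retardation",
    "tension",
    "uncooperativeness",
    "excitement",
    "distractibility",
    "motor_hyperactivity",
    "mannerisms_and_posturing",
)
POSITIVE_SYMPTOM_ITEMS = (
    "unusual_thought_content",
    "conceptual_disorganization",
    "hallucinatory_behavior",
    "grandiosity",
)

PROPORTIONAL_CHANGE = "proportional_change"
SLOPE = "slope"
POSITIVE_CHANGE = "positive_change"
OUTCOME_KINDS = (PROPORTIONAL_CHANGE, SLOPE, POSITIVE_CHANGE)


def proportional_change(y1: float, y2: float) -> float:
    """Proportional change score (y2 - y1) / y1.

    Undefined for a zero baseline; positive values mean the score went up.
    """
    if y1 == 0:
        raise ValueError("proportional change undefined for baseline score 0")
    return (y2 - y1) / y1


def slope_outcome(visit_months: Sequence[float], scores: Sequence[float]) -> float:
    """Ordinary least-squares slope of score on time (per month).

    Missing visits are simply absent from the inputs; at least two distinct
    time points are required.
    """
    t = np.asarray(visit_months, dtype=float)
    y = np.asarray(scores, dtype=float)
    if t.size != y.size:
        raise ValueError("visit_months and scores must have equal length")
    if t.size < 2 or np.all(t == t[0]):
        raise ValueError("slope needs at least 2 distinct time points")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def positive_symptom_score(item_scores: Mapping[str, float]) -> float:
    """Sum of the four positive-symptom items (range 4-28)."""
    missing = [k for k in POSITIVE_SYMPTOM_ITEMS if k not in item_scores]
    if missing:
        raise ValueError(f"missing positive-symptom items: {missing}")
    return float(sum(item_scores[k] for k in POSITIVE_SYMPTOM_ITEMS))


@dataclass
class OutcomeTable:
    """Long-format clinical scores plus optional item-level symptom scores.

    ``scores`` columns: subject_id, arm, scale, visit_month, score.
    ``items`` (optional) columns: subject_id, visit_month, one column per
    entry of :data:`BPRS_ITEMS`.
    """

    scores: pd.DataFrame
    items: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"subject_id", "arm", "scale", "visit_month", "score"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores table needs columns {sorted(required)}")
        dup = self.scores.duplicated(["subject_id", "scale", "visit_month"])
        if dup.any():
            raise ValueError("at most one score per (subject, scale, visit)")
        bad_scale = set(self.scores["scale"]) - {SOFAS, BPRS}
        if bad_scale:
            raise ValueError(f"unknown scales {bad_scale}")
        sof = self.scores.loc[self.scores["scale"] == SOFAS, "score"]
        if ((sof < SOFAS_RANGE[0]) | (sof > SOFAS_RANGE[1])).any():
            raise ValueError("SOFAS scores must lie in [0, 100]")
        bprs = self.scores.loc[self.scores["scale"] == BPRS, "score"]
        if ((bprs < BPRS_TOTAL_RANGE[0]) | (bprs > BPRS_TOTAL_RANGE[1])).any():
            raise ValueError("BPRS totals must lie in [24, 168]")
        if self.items is not None:
            missing = set(BPRS_ITEMS) - set(self.items.columns)
            if missing:
                raise ValueError(f"item table missing columns {sorted(missing)}")
            vals = self.items[list(BPRS_ITEMS)].to_numpy()
            if np.any(vals < BPRS_ITEM_RANGE[0] - 1e-9) or np.any(
                vals > BPRS_ITEM_RANGE[1] + 1e-9
            ):
                raise ValueError("item scores must lie in [1, 7]")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.scores["subject_id"].unique())

    def arm_of(self) -> pd.Series:
        return self.scores.groupby("subject_id")["arm"].first()

    def filter_arm(self, arm: str) -> "OutcomeTable":
        """Restrict to one treatment arm (subgroup evaluation)."""
        keep = self.scores["arm"] == arm
        scores = self.scores.loc[keep].reset_index(drop=True)
        items = None
        if self.items is not None:
            ids = set(scores["subject_id"])
            items = self.items[self.items["subject_id"].isin(ids)].reset_index(drop=True)
        return OutcomeTable(scores=scores, items=items)

    def filter_subjects(self, subject_ids: Iterable[str]) -> "OutcomeTable":
        ids = set(subject_ids)
        scores = self.scores[self.scores["subject_id"].isin(ids)].reset_index(drop=True)
        items = None
        if self.items is not None:
            items = self.items[self.items["subject_id"].isin(ids)].reset_index(drop=True)
        return OutcomeTable(scores=scores, items=items)

    @classmethod
    def from_csv(
        cls, scores_path: str | Path, items_path: str | Path | None = None
    ) -> "OutcomeTable":
        scores = pd.read_csv(scores_path, dtype={"subject_id": str})
        items = None
        if items_path is not None and Path(items_path).exists():
            items = pd.read_csv(items_path, dtype={"subject_id": str})
        return cls(scores=scores, items=items)

    def to_csv(self, scores_path: str | Path, items_path: str | Path | None = None) -> None:
        self.scores.to_csv(scores_path, index=False)
        if self.items is not None and items_path is not None:
            self.items.to_csv(items_path, index=False)


def _score_lookup(table: OutcomeTable, scale: str) -> pd.DataFrame:
    sub = table.scores[table.scores["scale"] == scale]
    return sub.pivot(index="subject_id", columns="visit_month", values="score")


def build_targets(
    table: OutcomeTable,
    measure: str,
    timepoint: int,
    outcome_kind: str = PROPORTIONAL_CHANGE,
) -> pd.Series:
    """One real prognostic target per retained subject.

    Parameters
    ----------
    table
        Scores (and, for the positive-symptom target, item scores).
    measure
        ``"functioning"`` (SOFAS) or ``"symptoms"`` (BPRS).
    timepoint
        Follow-up month, 6 or 12.  Ignored for ``outcome_kind="slope"``,
        which uses every available visit.
    outcome_kind
        ``"proportional_change"`` (default), ``"slope"`` or
        ``"positive_change"`` (proportional change of the 4-item
        positive-symptom sum; symptoms only).

    Subjects lacking the required scores are excluded and logged; nothing is
    imputed.  Raises if no subject survives the filter.
    """
    if measure not in MEASURE_TO_SCALE:
        raise ValueError(f"unknown measure {measure!r}")
    if outcome_kind not in OUTCOME_KINDS:
        raise ValueError(f"unknown outcome kind {outcome_kind!r}")
    if timepoint not in (6, 12):
        raise ValueError("timepoint must be 6 or 12 months")
    scale = MEASURE_TO_SCALE[measure]
    out: dict[str, float] = {}
    dropped: list[str] = []

    if outcome_kind == POSITIVE_CHANGE:
        if scale != BPRS:
            raise ValueError("positive-symptom targets require the symptom scale")
        if table.items is None:
            raise ValueError("positive-symptom targets require item-level scores")
        items = table.items.set_index(["subject_id", "visit_month"])
        for sid in table.subjects:
            try:
                base = items.loc[(sid, 0)]
                foll = items.loc[(sid, timepoint)]
            except KeyError:
                dropped.append(sid)
                continue
            y1 = positive_symptom_score(base)
            y2 = positive_symptom_score(foll)
            out[sid] = proportional_change(y1, y2)
    else:
        wide = _score_lookup(table, scale)
        for sid in table.subjects:
            if sid not in wide.index:
                dropped.append(sid)
                continue
            row = wide.loc[sid].dropna()
            if outcome_kind == PROPORTIONAL_CHANGE:
                if 0 not in row.index or timepoint not in row.index or row[0] == 0:
                    dropped.append(sid)
                    continue
                out[sid] = proportional_change(row[0], row[timepoint])
            else:  # slope over all available visits
                if len(row) < 2:
                    dropped.append(sid)
                    continue
                out[sid] = slope_outcome(row.index.to_numpy(float), row.to_numpy(float))

    if dropped:
        logger.info(
            "build_targets(%s, %dm, %s): dropped %d subject(s) with missing "
            "scores: %s",
            measure, timepoint, outcome_kind, len(dropped), dropped,
        )
    if not out:
        raise ValueError("no subject has the scores required for this target")
    s = pd.Series(out, name=f"{measure}_{timepoint}m_{outcome_kind}")
    s.index.name = "subject_id"
    return s
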