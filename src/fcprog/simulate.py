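"""Synthetic longitudinal functional-coupling cohorts with known ground truth.

The generator emulates the data structure of a small first-episode-psychosis
trial cohort: each subject contributes a baseline parcellated BOLD-like time
series, most contribute a 3-month follow-up series (missing-completely-at-
random attrition), and every subject carries two bounded clinical scales
(0-100 functioning, 24-item symptoms) measured at baseline, 6 and 12 months.

A sparse set of coupling edges carries a planted linear effect on the
outcome-change targets: the noiseless predictor is ``w . x`` where ``x`` is
the subject's upper-triangle baseline FC vector, and the effect size is
calibrated so that the squared correlation between target and noiseless
predictor equals ``effect_r2``.  The functioning scale loads positively on
the latent signal and the symptom scale negatively (better coupling profile,
more improvement, fewer symptoms).  Ground truth is retained for recovery
tests.

Regional time series are drawn from a subject-specific multivariate normal
built from a shared low-rank network backbone plus subject-level loading
perturbations, which yields realistic between-subject FC variance without
modelling hemodynamics.  Between-subject variation is dominated by a small
number of shared variation modes with subject-specific coefficients (plus a
weak idiosyncratic component), mirroring the well-replicated finding that
individual differences in FC concentrate along a few major axes; without
this low-dimensional structure a similarity-kernel predictor has nothing to
work with at clinical sample sizes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome, outcomes

logger = logging.getLogger(__name__)

# Cohort-level distributional anchors for the proportional-change targets:
# mean proportional changes of roughly +20%/+22% (functioning, 6/12 months)
# and -25%/-23% (symptoms), typical of medicated/psychosocially treated
# first-episode cohorts.
TARGET_MEAN = {
    (outcomes.SOFAS, 6): 0.20,
    (outcomes.SOFAS, 12): 0.22,
    (outcomes.BPRS, 6): -0.25,
    (outcomes.BPRS, 12): -0.23,
}
TARGET_SD = {outcomes.SOFAS: 0.25, outcomes.BPRS: 0.15}
# keep follow-up scores inside the scale bounds given midpoint baselines
TARGET_CLIP = {outcomes.SOFAS: 0.98, outcomes.BPRS: 0.74}
BASELINE_ANCHOR = {outcomes.SOFAS: 50.0, outcomes.BPRS: 96.0}


@dataclass(frozen=True)
class ScaleSpec:
    """Bounds of the two simulated clinical scales."""

    sofas_range: tuple[float, float] = outcomes.SOFAS_RANGE
    n_bprs_items: int = 24
    item_range: tuple[float, float] = outcomes.BPRS_ITEM_RANGE


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort the pipeline is designed for: 49 analysable
    subjects, 419 cortical+subcortical regions, a 3-month follow-up scan
    missing for roughly a quarter of subjects, and 1:1 randomization to a
    placebo-labelled arm.  ``effect_r2`` is the fraction of outcome-change
    variance explained by the planted FC effect (0 = null cohort).
    """

    n_subjects: int = 49
    n_regions: int = 419
    n_timepoints: int = 240
    effect_r2: float = 0.0
    n_causal_edges: int = 5
    attrition_fraction: float = 0.27
    scale_spec: ScaleSpec = field(default_factory=ScaleSpec)
    arm_fraction: float = 0.5
    scale_correlation: float = -0.3
    seed: int = 0
    # generative nuisance parameters (network backbone and its variation)
    n_latent: int = 4
    n_subject_modes: int = 3
    mode_strength: float = 0.5
    idiosyncratic_sd: float = 0.1
    followup_drift_sd: float = 0.2
    observation_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("effect_r2", "attrition_fraction", "arm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.scale_correlation <= 1.0:
            raise ValueError("scale_correlation must lie in [-1, 1]")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be at least 3")
        if self.n_subjects < 1 or self.n_regions < 2:
            raise ValueError("need at least 1 subject and 2 regions")
        max_edges = connectome.edge_count(self.n_regions)
        if self.n_causal_edges > max_edges:
            raise ValueError(
                f"n_causal_edges={self.n_causal_edges} exceeds the "
                f"{max_edges} available edges"
            )
        if self.effect_r2 > 0 and self.n_causal_edges == 0:
            raise ValueError("effect_r2 > 0 requires at least one causal edge")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    config: CohortConfig
    subject_ids: list[str]
    region_labels: tuple[str, ...]
    baseline_series: list[np.ndarray]
    followup_series: list[np.ndarray | None]
    arms: list[str]
    outcome_table: outcomes.OutcomeTable
    edge_weights: np.ndarray          # full-length planted weight vector w
    causal_edges: np.ndarray          # indices of the nonzero entries of w
    latent_signal: np.ndarray         # w . x per subject (noiseless predictor)
    targets: dict[tuple[str, int], np.ndarray]  # planted change targets

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def has_followup(self) -> np.ndarray:
        return np.array([s is not None for s in self.followup_series])

    def baseline_fc_vectors(self) -> tuple[np.ndarray, list[str]]:
        """Subjects-by-edges baseline FC feature matrix (all subjects)."""
        rows = [
            connectome.vectorize(
                connectome.compute_fc(ts, self.region_labels)
            ).values
            for ts in self.baseline_series
        ]
        return np.vstack(rows), list(self.subject_ids)

    def delta_fc_vectors(self) -> tuple[np.ndarray, list[str]]:
        """Subjects-by-edges delta-FC features (subjects with both scans)."""
        rows, ids = [], []
        for sid, base, foll in zip(
            self.subject_ids, self.baseline_series, self.followup_series
        ):
            if foll is None:
                continue
            b = connectome.compute_fc(base, self.region_labels)
            f = connectome.compute_fc(
                foll, self.region_labels, kind=connectome.FOLLOWUP_FC
            )
            rows.append(connectome.vectorize(connectome.delta_fc(b, f)).values)
            ids.append(sid)
        return np.vstack(rows), ids


def _simulate_series(
    rng: np.random.Generator,
    loadings: np.ndarray,
    n_timepoints: int,
    noise_sd: float,
) -> np.ndarray:
    """One scan: low-rank latent dynamics plus white observation noise."""
    n_regions, n_latent = loadings.shape
    latent = rng.standard_normal((n_latent, n_timepoints))
    noise = rng.standard_normal((n_regions, n_timepoints)) * noise_sd
    return loadings @ latent + noise


def _bounded_item_allocation(
    rng: np.random.Generator, total: float, n_items: int, lo: float, hi: float
) -> np.ndarray:
    """Split ``total`` into item scores in [lo, hi] that sum exactly to it.

    Draws Dirichlet proportions for the spread above the floor, then
    water-fills any allocation that would exceed the item ceiling.
    """
    spread = total - n_items * lo
    cap = hi - lo
    if spread < -1e-9 or spread > n_items * cap + 1e-9:
        raise ValueError("total outside the representable item range")
    p = rng.dirichlet(np.full(n_items, 50.0))
    alloc = p * spread
    for _ in range(100):
        excess = np.clip(alloc - cap, 0.0, None)
        if excess.sum() < 1e-12:
            break
        alloc = np.minimum(alloc, cap)
        headroom = cap - alloc
        alloc += excess.sum() * headroom / headroom.sum()
    return lo + np.minimum(alloc, cap)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one seeded cohort; identical config+seed gives identical data."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    R = config.n_regions
    labels = tuple(f"region_{i:03d}" for i in range(R))
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    # shared network backbone; between-subject variation = a few shared
    # modes with subject-specific coefficients + weak idiosyncratic noise
    backbone = rng.standard_normal((R, config.n_latent)) / np.sqrt(config.n_latent)
    modes = (
        rng.standard_normal((config.n_subject_modes, R, config.n_latent))
        * config.mode_strength
    )
    mode_coeff = rng.standard_normal((n, config.n_subject_modes))
    subj_load = (
        np.einsum("nm,mrk->nrk", mode_coeff, modes)
        + rng.standard_normal((n, R, config.n_latent)) * config.idiosyncratic_sd
    )
    baseline_series = [
        _simulate_series(
            rng, backbone + subj_load[i], config.n_timepoints,
            config.observation_noise_sd,
        )
        for i in range(n)
    ]

    # MCAR attrition: a seeded subset has no 3-month scan
    n_missing = int(round(config.attrition_fraction * n))
    missing = set(rng.choice(n, size=n_missing, replace=False).tolist())
    followup_series: list[np.ndarray | None] = []
    for i in range(n):
        if i in missing:
            followup_series.append(None)
        else:
            drift = (
                rng.standard_normal((R, config.n_latent))
                * config.followup_drift_sd
            )
            followup_series.append(
                _simulate_series(
                    rng, backbone + subj_load[i] + drift, config.n_timepoints,
                    config.observation_noise_sd,
                )
            )

    # planted sparse edge effect on the baseline FC vector
    n_edges = connectome.edge_count(R)
    w = np.zeros(n_edges)
    causal = np.sort(
        rng.choice(n_edges, size=config.n_causal_edges, replace=False)
    )
    w[causal] = 1.0
    X = np.vstack(
        [
            connectome.vectorize(connectome.compute_fc(ts, labels)).values
            for ts in baseline_series
        ]
    )
    s = X @ w
    if config.effect_r2 > 0 and n > 1 and s.std() > 0:
        s_std = (s - s.mean()) / s.std()
    else:
        s_std = np.zeros(n)
    rho = np.sqrt(config.effect_r2)
    noise_sd = np.sqrt(1.0 - config.effect_r2)

    # targets: shared latent signal, per-scale sign, correlated noise pair
    cov = np.array(
        [[1.0, config.scale_correlation], [config.scale_correlation, 1.0]]
    )
    targets: dict[tuple[str, int], np.ndarray] = {}
    for month in (6, 12):
        noise = rng.multivariate_normal(np.zeros(2), cov, size=n) * noise_sd
        z_sofas = rho * s_std + noise[:, 0]
        z_bprs = -rho * s_std + noise[:, 1]
        for scale, z in ((outcomes.SOFAS, z_sofas), (outcomes.BPRS, z_bprs)):
            t = TARGET_MEAN[(scale, month)] + TARGET_SD[scale] * z
            clip = TARGET_CLIP[scale]
            n_clipped = int(np.sum(np.abs(t) > clip))
            if n_clipped:
                logger.info(
                    "clipped %d extreme %s %dm targets to +/-%g",
                    n_clipped, scale, month, clip,
                )
            targets[(scale, month)] = np.clip(t, -clip, clip)

    # arm labels (randomized assignment)
    n_placebo = int(round(config.arm_fraction * n))
    order = rng.permutation(n)
    arms = [outcomes.MEDICATION] * n
    for i in order[:n_placebo]:
        arms[i] = outcomes.PLACEBO

    # score tables: midpoint-anchored baselines, follow-ups derived so the
    # proportional-change formula reproduces the planted target exactly
    rows = []
    item_rows = []
    lo, hi = config.scale_spec.item_range
    n_items = config.scale_spec.n_bprs_items
    for i, sid in enumerate(subject_ids):
        for scale in (outcomes.SOFAS, outcomes.BPRS):
            y1 = BASELINE_ANCHOR[scale]
            visit_scores = {0: y1}
            for month in (6, 12):
                visit_scores[month] = y1 * (1.0 + targets[(scale, month)][i])
            for month, score in visit_scores.items():
                rows.append(
                    {
                        "subject_id": sid,
                        "arm": arms[i],
                        "scale": scale,
                        "visit_month": month,
                        "score": score,
                    }
                )
            if scale == outcomes.BPRS:
                for month, score in visit_scores.items():
                    alloc = _bounded_item_allocation(rng, score, n_items, lo, hi)
                    row: dict[str, object] = {
                        "subject_id": sid,
                        "visit_month": month,
                    }
                    row.update(dict(zip(outcomes.BPRS_ITEMS, alloc)))
                    item_rows.append(row)

    table = outcomes.OutcomeTable(
        scores=pd.DataFrame(rows), items=pd.DataFrame(item_rows)
    )
    return SyntheticCohort(
        config=config,
        subject_ids=subject_ids,
        region_labels=labels,
        baseline_series=baseline_series,
        followup_series=followup_series,
        arms=arms,
        outcome_table=table,
        edge_weights=w,
        causal_edges=causal,
        latent_signal=s,
        targets={
            (scale, month): targets[(scale, month)]
            for scale in (outcomes.SOFAS, outcomes.BPRS)
            for month in (6, 12)
        },
    )


def generate_fc_features(
    n_subjects: int,
    n_regions: int,
    n_timepoints: int,
    seed: int,
    n_latent: int = 4,
    n_subject_modes: int = 3,
    mode_strength: float = 0.5,
    idiosyncratic_sd: float = 0.1,
    observation_noise_sd: float = 1.0,
    structure_seed: int | None = None,
) -> np.ndarray:
    """Subjects-by-edges FC feature matrix from the same generative family.

    Used for large synthetic source cohorts (transfer-learning bank training)
    where the longitudinal/clinical scaffolding of a full cohort is not
    needed.  ``structure_seed`` seeds the shared population structure (the
    network backbone and the variation modes) separately from the subjects,
    so several cohorts can be drawn from one population — the premise of any
    transfer-learning experiment.
    """
    srng = np.random.default_rng(
        seed if structure_seed is None else structure_seed
    )
    backbone = srng.standard_normal((n_regions, n_latent)) / np.sqrt(n_latent)
    modes = srng.standard_normal((n_subject_modes, n_regions, n_latent)) * mode_strength
    rng = np.random.default_rng(seed)
    coeff = rng.standard_normal((n_subjects, n_subject_modes))
    loadings = (
        backbone
        + np.einsum("nm,mrk->nrk", coeff, modes)
        + rng.standard_normal((n_subjects, n_regions, n_latent)) * idiosyncratic_sd
    )
    latent = rng.standard_normal((n_subjects, n_latent, n_timepoints))
    series = np.einsum("nrk,nkt->nrt", loadings, latent)
    series += rng.standard_normal(series.shape) * observation_noise_sd
    # batched per-subject Pearson correlation across regions
    series -= series.mean(axis=2, keepdims=True)
    series /= np.linalg.norm(series, axis=2, keepdims=True)
    fc = np.einsum("nrt,nst->nrs", series, series)
    iu = np.triu_indices(n_regions, k=1)
    return np.clip(fc[:, iu[0], iu[1]], -1.0, 1.0)


# ---------------------------------------------------------------------------
# on-disk representation


def _write_series(path: Path, labels: tuple[str, ...], ts: np.ndarray) -> None:
    with path.open("w") as fh:
        fh.write("region\t" + "\t".join(str(j) for j in range(ts.shape[1])) + "\n")
        for label, row in zip(labels, ts):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def _read_series(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    labels, rows = [], []
    with path.open() as fh:
        fh.readline()  # sample-index header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return tuple(labels), np.array(rows)


def export_cohort(
    cohort: SyntheticCohort, directory: str | Path, force: bool = False
) -> Path:
    """Write the cohort as delimited text files plus a ground-truth record.

    Layout: one ``<subject>_baseline_timeseries.tsv`` per subject, one
    ``<subject>_followup_timeseries.tsv`` per subject with a 3-month scan,
    ``outcomes.csv`` (long format), ``bprs_items.csv`` and
    ``ground_truth.json``.  Refuses to overwrite an existing directory
    unless ``force`` is set.
    """
    directory = Path(directory)
    if directory.exists():
        if not force:
            raise FileExistsError(
                f"{directory} exists; pass force=True to overwrite"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True)
    for sid, base, foll in zip(
        cohort.subject_ids, cohort.baseline_series, cohort.followup_series
    ):
        _write_series(
            directory / f"{sid}_baseline_timeseries.tsv", cohort.region_labels, base
        )
        if foll is not None:
            _write_series(
                directory / f"{sid}_followup_timeseries.tsv",
                cohort.region_labels,
                foll,
            )
    cohort.outcome_table.to_csv(
        directory / "outcomes.csv", directory / "bprs_items.csv"
    )
    cfg = dataclasses.asdict(cohort.config)
    truth = {
        "config": cfg,
        "subject_ids": cohort.subject_ids,
        "causal_edges": cohort.causal_edges.tolist(),
        "causal_weights": cohort.edge_weights[cohort.causal_edges].tolist(),
        "latent_signal": cohort.latent_signal.tolist(),
        "targets": {
            f"{scale}_{month}": vals.tolist()
            for (scale, month), vals in cohort.targets.items()
        },
    }
    with (directory / "ground_truth.json").open("w") as fh:
        json.dump(truth, fh, indent=1)
    return directory


def load_cohort(directory: str | Path) -> SyntheticCohort:
    """Round-trip loader for :func:`export_cohort` output."""
    directory = Path(directory)
    with (directory / "ground_truth.json").open() as fh:
        truth = json.load(fh)
    cfg_dict = dict(truth["config"])
    cfg_dict["scale_spec"] = ScaleSpec(
        sofas_range=tuple(cfg_dict["scale_spec"]["sofas_range"]),
        n_bprs_items=cfg_dict["scale_spec"]["n_bprs_items"],
        item_range=tuple(cfg_dict["scale_spec"]["item_range"]),
    )
    config = CohortConfig(**cfg_dict)
    subject_ids = truth["subject_ids"]
    baseline_series, followup_series = [], []
    region_labels: tuple[str, ...] = ()
    for sid in subject_ids:
        region_labels, ts = _read_series(directory / f"{sid}_baseline_timeseries.tsv")
        baseline_series.append(ts)
        fpath = directory / f"{sid}_followup_timeseries.tsv"
        followup_series.append(_read_series(fpath)[1] if fpath.exists() else None)
    table = outcomes.OutcomeTable.from_csv(
        directory / "outcomes.csv", directory / "bprs_items.csv"
    )
    n_edges = connectome.edge_count(config.n_regions)
    w = np.zeros(n_edges)
    causal = np.array(truth["causal_edges"], dtype=int)
    w[causal] = np.array(truth["causal_weights"])
    arm_map = table.arm_of()
    targets = {}
    for key, vals in truth["targets"].items():
        scale, month = key.rsplit("_", 1)
        targets[(scale, int(month))] = np.array(vals)
    return SyntheticCohort(
        config=config,
        subject_ids=subject_ids,
        region_labels=region_labels,
        baseline_series=baseline_series,
        followup_series=followup_series,
        arms=[arm_map[sid] for sid in subject_ids],
        outcome_table=table,
        edge_weights=w,
        causal_edges=causal,
        latent_signal=np.array(truth["latent_signal"]),
        targets=targets,
    )
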