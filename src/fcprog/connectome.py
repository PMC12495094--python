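"""Functional-coupling (FC) matrices and their fixed-order edge vectorization.

An FC matrix holds the Pearson correlation between every pair of regional
activity time series from one scan.  A delta-FC matrix is the element-wise
difference between a follow-up and a baseline FC matrix for the same subject
and region set.  All predictors downstream consume the row-major strict
upper-triangle vectorization of these matrices, so one canonical edge order
is fixed here and used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

BASELINE_FC = "baseline_fc"
FOLLOWUP_FC = "followup_fc"
DELTA_FC = "delta_fc"
_KINDS = (BASELINE_FC, FOLLOWUP_FC, DELTA_FC)


def edge_count(n_regions: int) -> int:
    """Number of unordered region pairs, n(n-1)/2."""
    return n_regions * (n_regions - 1) // 2


def edge_index(n_regions: int) -> np.ndarray:
    """Canonical (i, j) pairs, i < j, row-major over the strict upper triangle.

    Returns an integer array of shape (2, n_edges); column k is the k-th edge.
    """
    return np.vstack(np.triu_indices(n_regions, k=1))


@dataclass
class FCMatrix:
    """Symmetric region-by-region coupling matrix for one subject-visit."""

    values: np.ndarray
    region_labels: tuple[str, ...]
    kind: str = BASELINE_FC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = tuple(self.region_labels)
        n = len(self.region_labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} region labels"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"unknown FC kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if self.kind == DELTA_FC:
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
                raise ValueError("delta-FC diagonal must be 0")
            if np.any(np.abs(self.values) > 2 + 1e-10):
                raise ValueError("delta-FC entries must lie in [-2, 2]")
        else:
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
                raise ValueError("FC diagonal must be 1")
            if np.any(np.abs(self.values) > 1 + 1e-10):
                raise ValueError("FC entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass
class FCVector:
    """Fixed-order upper-triangle vectorization of an FCMatrix."""

    values: np.ndarray
    edge_index: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.edge_index = np.asarray(self.edge_index)
        if self.values.ndim != 1:
            raise ValueError("FCVector values must be one-dimensional")
        if self.edge_index.shape != (2, self.values.size):
            raise ValueError("edge_index shape must be (2, n_edges)")


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"region_{i:03d}" for i in range(n))


def compute_fc(
    timeseries: np.ndarray,
    region_labels: Sequence[str] | None = None,
    kind: str = BASELINE_FC,
) -> FCMatrix:
    """Pearson correlation between every pair of regional time series.

    Parameters
    ----------
    timeseries
        Array of shape (n_regions, n_timepoints), one row per region.
    region_labels
        Optional region names; generated if omitted.
    kind
        ``"baseline_fc"`` or ``"followup_fc"``.

    Raises
    ------
    ValueError
        If fewer than 3 time points are supplied, or if any region has zero
        temporal variance (a degenerate scan; the error names the region).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D regions x samples array")
    n_regions, n_t = ts.shape
    if n_t < 3:
        raise ValueError(f"need at least 3 time points, got {n_t}")
    if kind == DELTA_FC:
        raise ValueError("delta-FC matrices come from delta_fc(), not compute_fc()")
    labels = tuple(region_labels) if region_labels is not None else _default_labels(n_regions)
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"region {labels[dead[0]]!r} (index {dead[0]}) has zero temporal "
            "variance; correlation is undefined"
        )
    c = np.corrcoef(ts)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FCMatrix(values=c, region_labels=labels, kind=kind)


def delta_fc(baseline: FCMatrix, followup: FCMatrix) -> FCMatrix:
    """Follow-up minus baseline FC, the subject's coupling change matrix."""
    if baseline.kind == DELTA_FC or followup.kind == DELTA_FC:
        raise ValueError("delta_fc operands must be plain FC matrices")
    if baseline.region_labels != followup.region_labels:
        raise ValueError("region labels of baseline and follow-up do not match")
    return FCMatrix(
        values=followup.values - baseline.values,
        region_labels=baseline.region_labels,
        kind=DELTA_FC,
    )


def vectorize(matrix: FCMatrix) -> FCVector:
    """Row-major strict upper-triangle vector of an FC matrix."""
    idx = edge_index(matrix.n_regions)
    return FCVector(values=matrix.values[idx[0], idx[1]], edge_index=idx)


def devectorize(
    vector: FCVector,
    region_labels: Sequence[str] | None = None,
    kind: str = BASELINE_FC,
) -> FCMatrix:
    """Inverse of :func:`vectorize`; rebuilds the symmetric matrix."""
    n_edges = vector.values.size
    # solve n(n-1)/2 = n_edges
    n = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if edge_count(n) != n_edges:
        raise ValueError(f"{n_edges} edges is not a triangular number")
    m = np.zeros((n, n))
    idx = vector.edge_index
    m[idx[0], idx[1]] = vector.values
    m = m + m.T
    if kind != DELTA_FC:
        np.fill_diagonal(m, 1.0)
    labels = tuple(region_labels) if region_labels is not None else _default_labels(n)
    return FCMatrix(values=m, region_labels=labels, kind=kind)


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform, arctanh with clipping away from |r| = 1.

    Off by default throughout the package (raw Pearson entries are the
    canonical feature); exposed for the standardization variant.
    """
    return np.arctanh(np.clip(values, -1 + 1e-12, 1 - 1e-12))


def write_fc_matrix(matrix: FCMatrix, path: str | Path) -> None:
    """Write a square delimited text file with a label header row/column."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("region\t" + "\t".join(matrix.region_labels) + "\n")
        for label, row in zip(matrix.region_labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_fc_matrix(path: str | Path, kind: str = BASELINE_FC) -> FCMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if labels != header:
        raise ValueError("row and column labels disagree")
    return FCMatrix(values=np.array(rows), region_labels=tuple(labels), kind=kind)
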