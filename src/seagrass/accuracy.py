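"""Error-matrix accuracy assessment.

Matrix orientation is fixed throughout: rows are the classified (predicted)
data, columns are the reference (validation) data.  Producer accuracy is the
diagonal over the *column* total, user accuracy the diagonal over the *row*
total, overall accuracy the trace over the grand total, and kappa the usual
chance-corrected agreement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import GroundTruthPoints
from .rasters import CLASS_TABLE, HabitatMap, sample_at_points

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "build_error_matrix",
    "overall_accuracy",
    "producer_user_accuracy",
    "kappa",
    "accuracy_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ErrorMatrix:
    """Square class-by-class count table; rows predicted, columns reference."""

    classes: tuple[int, ...]
    counts: np.ndarray
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_TABLE))

    def __post_init__(self) -> None:
        self.classes = tuple(int(c) for c in self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {k} classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        names = [self.class_names.get(c, str(c)) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "predicted\\reference"
        df.to_csv(path)


def build_error_matrix(
    predicted: HabitatMap,
    reference: GroundTruthPoints,
    classes: tuple[int, ...] | None = None,
) -> ErrorMatrix:
    """Cross-tabulate the classified map against reference points.

    ``counts[p][r]`` is the number of reference points of class ``r``
    predicted as ``p``.  Points that fall off-grid or on unclassified
    (nodata) pixels are dropped with a logged count.
    """
    if len(reference) == 0:
        raise ValueError("reference point set is empty")
    if classes is None:
        classes = tuple(sorted(predicted.class_table))
    pred, usable = sample_at_points(
        predicted.labels.astype(float), predicted.grid, reference.x, reference.y
    )
    idx = np.flatnonzero(usable)
    on_nodata = pred[idx] == 0
    usable[idx[on_nodata]] = False
    n_drop = int(np.count_nonzero(~usable))
    if n_drop:
        logger.info("build_error_matrix: %d reference points dropped", n_drop)
    if not usable.any():
        raise ValueError("no usable reference points on classified pixels")
    pred = pred[usable].astype(int)
    ref = reference.label[usable]
    pos = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for p, r in zip(pred, ref):
        counts[pos[p], pos[r]] += 1
    return ErrorMatrix(classes=classes, counts=counts, class_names=dict(predicted.class_table))


def overall_accuracy(m: ErrorMatrix) -> float:
    """Percent of reference samples on the diagonal: 100 * trace / n."""
    if m.n_total == 0:
        raise ValueError("empty error matrix")
    return 100.0 * float(np.trace(m.counts)) / m.n_total


def producer_user_accuracy(m: ErrorMatrix) -> dict[int, tuple[float, float]]:
    """Per-class (producer_pct, user_pct).

    Producer = 100 * diagonal / column total (reference marginal); user =
    100 * diagonal / row total (predicted marginal).  Classes with a zero
    marginal get NaN for the corresponding statistic rather than an error.
    """
    diag = np.diag(m.counts).astype(float)
    col = m.col_totals.astype(float)
    row = m.row_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        producer = np.where(col > 0, 100.0 * diag / col, np.nan)
        user = np.where(row > 0, 100.0 * diag / row, np.nan)
    return {c: (float(producer[i]), float(user[i])) for i, c in enumerate(m.classes)}


def kappa(m: ErrorMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) with p_e from the marginals.

    Returns NaN for the degenerate case p_e = 1.
    """
    n = m.n_total
    if n == 0:
        raise ValueError("empty error matrix")
    p_o = float(np.trace(m.counts)) / n
    p_e = float(np.sum(m.row_totals * m.col_totals)) / (n * n)
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AccuracyReport:
    """Overall / producer / user percentages and kappa for one error matrix."""

    overall_pct: float
    producer_pct: dict[int, float]
    user_pct: dict[int, float]
    kappa: float
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_TABLE))

    def to_dict(self, ndigits: int = 1) -> dict:
        def _round(v: float):
            return None if np.isnan(v) else round(v, ndigits)

        return {
            "overall_pct": _round(self.overall_pct),
            "producer_pct": {
                self.class_names.get(c, str(c)): _round(v) for c, v in self.producer_pct.items()
            },
            "user_pct": {
                self.class_names.get(c, str(c)): _round(v) for c, v in self.user_pct.items()
            },
            "kappa": None if np.isnan(self.kappa) else round(self.kappa, 3),
        }

    def to_json(self, path, ndigits: int = 1) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(ndigits), fh, indent=2)


def accuracy_report(m: ErrorMatrix) -> AccuracyReport:
    """Compute the full accuracy report from an error matrix."""
    pu = producer_user_accuracy(m)
    return AccuracyReport(
        overall_pct=overall_accuracy(m),
        producer_pct={c: pu[c][0] for c in m.classes},
        user_pct={c: pu[c][1] for c in m.classes},
        kappa=kappa(m),
        class_names=dict(m.class_names),
    )
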