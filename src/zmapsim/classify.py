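"""Contrast classification from pairwise score matrices.

Each query contrast (a row of scores against every target contrast) is
assigned the target with the highest *absolute* score — abs-descending
ranking.  Not-comparable entries (NaN) rank below every comparable
entry; a row with no comparable entry yields no prediction and counts
as incorrect.  Ties on |score| break to the lowest column index and are
logged, purely for determinism.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NO_PREDICTION",
    "ScoreMatrix",
    "AccuracySummary",
    "ConfusionMatrix",
    "predict",
    "evaluate_subsample",
    "aggregate",
    "chance_level",
]

#: sentinel index for a row with no comparable score
NO_PREDICTION = -1


@dataclasses.dataclass
class ScoreMatrix:
    """Square matrix of scores: rows = query contrasts (group A,
    unthresholded), columns = target contrasts (group B)."""

    values: np.ndarray
    contrast_ids: list[str]
    condition: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.contrast_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} contrast ids"
            )


@dataclasses.dataclass
class AccuracySummary:
    condition: dict
    overall_mean: float
    ci_low: float
    ci_high: float
    n_subsamples: int
    per_contrast_mean: np.ndarray
    per_contrast_sd: np.ndarray
    contrast_ids: list[str]


@dataclasses.dataclass
class ConfusionMatrix:
    """Counts of (true contrast, predicted contrast) over subsamples.

    ``counts`` has one extra final column for no-prediction rows, so
    every row sums to the number of subsamples.
    """

    condition: dict
    counts: np.ndarray
    contrast_ids: list[str]

    @property
    def diagonal_accuracy(self) -> float:
        n = len(self.contrast_ids)
        return float(np.trace(self.counts[:, :n]) / self.counts.sum())


def predict(row: Sequence[float]) -> int:
    """Predicted target index for one query row, or NO_PREDICTION.

    The winner is the maximum |score| among comparable (finite)
    entries.  Equal |score| ties break to the lowest index.
    """
    row = np.asarray(row, dtype=float)
    if row.size < 1:
        raise ValueError("row must have at least one entry")
    comparable = np.isfinite(row)
    if not comparable.any():
        return NO_PREDICTION
    mag = np.where(comparable, np.abs(row), -np.inf)
    best = int(np.argmax(mag))  # argmax returns the first maximum
    if np.sum(mag == mag[best]) > 1:
        logger.info("tie on |score|=%g broken to column %d", mag[best], best)
    return best


def evaluate_subsample(
    matrix: ScoreMatrix,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Classify every query row of one subsample.

    Returns (predictions, correctness, accuracy): prediction per row
    (NO_PREDICTION where nothing was comparable), the 0/1 correctness
    vector (row i correct iff predicted i), and their mean.
    """
    n = len(matrix.contrast_ids)
    predictions = np.array([predict(matrix.values[i]) for i in range(n)])
    correctness = (predictions == np.arange(n)).astype(float)
    return predictions, correctness, float(correctness.mean())


def aggregate(
    predictions: np.ndarray,
    contrast_ids: Sequence[str],
    condition: dict | None = None,
) -> tuple[AccuracySummary, ConfusionMatrix]:
    """Aggregate per-subsample predictions into summary and confusion.

    ``predictions`` is (n_subsamples, n_contrasts) of predicted column
    indices (NO_PREDICTION allowed).  The 95% interval on the overall
    accuracy uses the normal approximation mean +/- 1.96 * sd/sqrt(n)
    over the subsample accuracies; with a single subsample it collapses
    to the mean with a warning.
    """
    predictions = np.asarray(predictions)
    if predictions.ndim != 2:
        raise ValueError("predictions must be (n_subsamples, n_contrasts)")
    n_sub, n_con = predictions.shape
    if n_con != len(contrast_ids):
        raise ValueError("contrast_ids length mismatch")
    condition = dict(condition or {})

    correctness = (predictions == np.arange(n_con)).astype(float)
    sub_acc = correctness.mean(axis=1)
    overall = float(sub_acc.mean())
    if n_sub >= 2:
        half = 1.96 * sub_acc.std(ddof=1) / np.sqrt(n_sub)
    else:
        warnings.warn(
            "single subsample: 95% interval degenerates to the mean",
            stacklevel=2,
        )
        half = 0.0
    summary = AccuracySummary(
        condition=condition,
        overall_mean=overall,
        ci_low=overall - half,
        ci_high=overall + half,
        n_subsamples=n_sub,
        per_contrast_mean=correctness.mean(axis=0),
        per_contrast_sd=correctness.std(axis=0, ddof=0),
        contrast_ids=list(contrast_ids),
    )

    counts = np.zeros((n_con, n_con + 1), dtype=int)
    for row in predictions:
        for true_idx, pred in enumerate(row):
            col = n_con if pred == NO_PREDICTION else int(pred)
            counts[true_idx, col] += 1
    confusion = ConfusionMatrix(
        condition=condition, counts=counts, contrast_ids=list(contrast_ids)
    )
    return summary, confusion


def chance_level(n_contrasts: int) -> float:
    """Expected accuracy of uniform random assignment: 1/n."""
    if n_contrasts < 1:
        raise ValueError("n_contrasts must be >= 1")
    return 1.0 / n_contrasts
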