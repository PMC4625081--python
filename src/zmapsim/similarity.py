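"""Pairwise similarity of an unthresholded query map against a
(possibly thresholded) target map.

Two strategies decide which voxels enter the comparison:

* **CCA** (complete case analysis): the intersection of voxels that are
  inside the mask and non-zero, non-NaN in *both* images.
* **SVI** (single-value imputation): every mask voxel, with empty/NaN
  values replaced by zero in both vectors.

A comparison is *not comparable* (score NaN) when no voxels survive,
when fewer than three paired voxels exist, or when either vector has
zero variance.  Under positive-only directionality the positive filter
is applied to both images — including the unthresholded query — before
the comparison set is built.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .groupstats import BrainMask, ZStatMap
from .thresholding import ThresholdSpec, apply_threshold

__all__ = [
    "STRATEGIES",
    "METRICS",
    "SimilarityScore",
    "build_comparison_set",
    "pearson",
    "spearman",
    "compare",
]

STRATEGIES = ("CCA", "SVI")
METRICS = ("pearson", "spearman")

#: fewer paired voxels than this is not comparable
MIN_VOXELS = 3


@dataclasses.dataclass(frozen=True)
class SimilarityScore:
    """One pairwise comparison; ``value`` is NaN when not comparable."""

    value: float
    metric: str
    strategy: str
    n_voxels: int
    query_contrast: str
    target_contrast: str

    @property
    def comparable(self) -> bool:
        return math.isfinite(self.value)


def _positive_only(vol: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.where(vol > 0, vol, np.nan)


def build_comparison_set(
    map_a: ZStatMap,
    map_b: ZStatMap,
    strategy: str,
    mask: BrainMask,
    direction: str = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """Extract index-aligned value vectors (xA, xB) for one comparison.

    ``map_a`` is the unthresholded query, ``map_b`` the target.  With
    ``direction="positive"`` non-positive values are first removed from
    both maps.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if map_a.volume.shape != map_b.volume.shape:
        raise ValueError("query and target shapes differ")
    if map_a.volume.shape != mask.volume.shape:
        raise ValueError("map and mask shapes differ")
    a = map_a.volume
    b = map_b.volume
    if direction == "positive":
        a = _positive_only(a)
        b = _positive_only(b)
    elif direction != "both":
        raise ValueError("direction must be 'both' or 'positive'")
    m = mask.volume
    if strategy == "CCA":
        with np.errstate(invalid="ignore"):
            idx = (m & np.isfinite(a) & np.isfinite(b)
                   & (a != 0) & (b != 0))
        return a[idx], b[idx]
    # SVI: the comparison universe is the whole brain mask
    xa = np.nan_to_num(a[m], nan=0.0)
    xb = np.nan_to_num(b[m], nan=0.0)
    return xa, xb


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample product-moment correlation; NaN when not comparable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < MIN_VOXELS or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Rank correlation (average ranks on ties); NaN when not comparable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < MIN_VOXELS or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


_METRIC_FN = {"pearson": pearson, "spearman": spearman}


def compare(
    map_a: ZStatMap,
    map_b: ZStatMap,
    strategy: str,
    metric: str,
    mask: BrainMask,
    direction: str = "both",
) -> SimilarityScore:
    """Score one query/target pair under a strategy, metric, direction.

    The query must be unthresholded (a retrieval query is assumed to be
    a full map); the target may carry any threshold.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if map_a.threshold_applied is not None and \
            not map_a.threshold_applied.is_noop:
        raise ValueError("query map must be unthresholded")
    xa, xb = build_comparison_set(map_a, map_b, strategy, mask, direction)
    value = _METRIC_FN[metric](xa, xb)
    return SimilarityScore(
        value=value,
        metric=metric,
        strategy=strategy,
        n_voxels=int(xa.size),
        query_contrast=map_a.contrast_id,
        target_contrast=map_b.contrast_id,
    )


def threshold_for_direction(zmap: ZStatMap, level: float,
                            direction: str) -> ZStatMap:
    """Convenience: threshold a map at ``level`` with ``direction``."""
    return apply_threshold(zmap, ThresholdSpec(level=level,
                                               direction=direction))
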