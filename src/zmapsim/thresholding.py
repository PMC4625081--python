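"""Threshold sweeps over Z maps and voxel-survival bookkeeping.

Two directionalities are supported:

* ``both`` — keep voxels with value strictly above +T or strictly below
  -T.  At T = 0 this is a no-op: the map is returned unchanged, exact
  zeros included.
* ``positive`` — keep voxels strictly above +T.  This removes every
  non-positive value at any level, **including T = 0**: positive-only
  analysis eliminates negative values (and exact zeros) outright rather
  than merely cutting at the level.

Inequalities are strict; values equal to +/-T are removed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .groupstats import BrainMask, ZStatMap

__all__ = ["ThresholdSpec", "DEFAULT_SWEEP", "apply_threshold",
           "survival_fraction"]

#: the default sweep: 0.0 (no threshold) to 13.0 in steps of 1.0
DEFAULT_SWEEP: tuple[float, ...] = tuple(float(t) for t in range(14))

_DIRECTIONS = ("both", "positive")


@dataclasses.dataclass(frozen=True)
class ThresholdSpec:
    level: float
    direction: str = "both"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("threshold level must be >= 0")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")

    @property
    def is_noop(self) -> bool:
        return self.level == 0.0 and self.direction == "both"


def _check_composable(prev: ThresholdSpec | None, new: ThresholdSpec) -> None:
    if prev is None or prev.is_noop:
        return
    if prev.level > new.level:
        raise ValueError(
            f"map already thresholded at {prev.level} > requested {new.level}"
        )
    if prev.direction == "positive" and new.direction == "both":
        raise ValueError(
            "cannot apply a two-sided threshold after a positive-only one"
        )


def apply_threshold(zmap: ZStatMap, spec: ThresholdSpec) -> ZStatMap:
    """Return a new Z map with non-surviving voxels set empty.

    Surviving values are unchanged.  Thresholding is idempotent and
    composes: T1 then T2 >= T1 (same direction) equals T2 alone.
    """
    _check_composable(zmap.threshold_applied, spec)
    vol = zmap.volume
    if spec.is_noop:
        out = vol.copy()
    else:
        with np.errstate(invalid="ignore"):
            if spec.direction == "both":
                keep = (vol > spec.level) | (vol < -spec.level)
            else:
                keep = vol > spec.level
        out = np.where(keep, vol, np.nan)
    return ZStatMap(
        contrast_id=zmap.contrast_id,
        group_label=zmap.group_label,
        volume=out,
        threshold_applied=spec,
    )


def survival_fraction(zmap: ZStatMap, mask: BrainMask) -> float:
    """Fraction of mask voxels that are non-empty in the map."""
    if zmap.volume.shape != mask.volume.shape:
        raise ValueError("map and mask shapes differ")
    n_mask = mask.n_voxels
    if n_mask == 0:
        raise ValueError("empty mask")
    surviving = np.isfinite(zmap.volume) & mask.volume
    return float(surviving.sum() / n_mask)
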