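"""Group-level statistics: voxelwise one-sample t maps and the
tail-precise t-to-Z conversion.

Empty voxels (outside the mask, zero-variance, or removed by a later
threshold) are carried as quiet NaN in memory; NIfTI export writes 0 at
empty voxels with the mask alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import special, stats

from .cohort import SubjectMap

logger = logging.getLogger(__name__)

__all__ = [
    "BrainMask",
    "TStatMap",
    "ZStatMap",
    "one_sample_t",
    "t_to_z",
    "t_to_z_values",
    "save_zmap",
    "load_zmap",
]


@dataclasses.dataclass
class BrainMask:
    volume: np.ndarray  # boolean
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume).astype(bool)
        if int(self.volume.sum()) < 3:
            raise ValueError("brain mask must contain at least 3 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclasses.dataclass
class TStatMap:
    contrast_id: str
    group_label: str
    volume: np.ndarray  # t values, NaN = empty
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclasses.dataclass
class ZStatMap:
    contrast_id: str
    group_label: str
    volume: np.ndarray  # Z values, NaN = empty
    threshold_applied: "object | None" = None  # ThresholdSpec, set downstream


def one_sample_t(maps: Sequence[SubjectMap], mask: BrainMask) -> TStatMap:
    """Voxelwise one-sample t statistic across subjects.

    t = x_bar / (s / sqrt(n)) with s the unbiased (n-1) standard
    deviation; df = n - 1.  Voxels outside the mask are empty (NaN);
    zero-variance voxels are set empty and counted in a log summary.
    """
    if len(maps) < 2:
        raise ValueError("one_sample_t needs at least 2 subject maps")
    contrast_ids = {m.contrast_id for m in maps}
    if len(contrast_ids) != 1:
        raise ValueError(f"maps span multiple contrasts: {contrast_ids}")
    shapes = {m.volume.shape for m in maps}
    if len(shapes) != 1 or maps[0].volume.shape != mask.volume.shape:
        raise ValueError("subject maps and mask must share one grid shape")

    data = np.stack([m.volume for m in maps])
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & mask.volume
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.warning(
            "one_sample_t: %d zero-variance voxel(s) in mask set empty "
            "(contrast %s)", n_zero, maps[0].contrast_id
        )
    t = np.where(mask.volume & ~zero_var, t, np.nan)
    return TStatMap(
        contrast_id=maps[0].contrast_id,
        group_label="",
        volume=t,
        df=n - 1,
    )


# log of the leading constant of the Student-t upper-tail power law:
# sf(t; df) ~ C(df) * t**(-df)  as t -> inf
def _log_tail_const(df: float) -> float:
    return (
        special.gammaln((df + 1) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        + (df - 1) / 2.0 * np.log(df)
    )


def t_to_z_values(t: np.ndarray, df: int) -> np.ndarray:
    """Tail-precise conversion of t statistics to standard-normal Z.

    Z = Phi^-1(F_t(t; df)) evaluated per tail in log-probability space:
    the tail probability of |t| is computed as a log (log-sf of the t
    distribution), and the inverse normal accepts that log directly, so
    no probability is ever rounded to 0 or 1.  By symmetry of both
    distributions Z(-t) = -Z(t) exactly, and Z is finite for every
    finite t — a naive Phi^-1(F_t(t)) in linear space returns +/-inf
    once F_t rounds to 1 (around |t| = 13 at df = 45).

    NaN entries (empty voxels) propagate.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, np.nan)
    finite = np.isfinite(t)
    at = np.abs(t[finite])
    with np.errstate(divide="ignore"):
        log_sf = stats.t.logsf(at, df)
    # extreme |t| underflows even logsf; switch to the power-law tail
    bad = ~np.isfinite(log_sf)
    if np.any(bad):
        log_sf[bad] = _log_tail_const(df) - df * np.log(at[bad])
    z_mag = -special.ndtri_exp(log_sf)
    out[finite] = np.sign(t[finite]) * z_mag
    return out


def t_to_z(tmap: TStatMap) -> ZStatMap:
    """Convert a t map to a Z map, preserving empties."""
    return ZStatMap(
        contrast_id=tmap.contrast_id,
        group_label=tmap.group_label,
        volume=t_to_z_values(tmap.volume, tmap.df),
        threshold_applied=None,
    )


def save_zmap(zmap: ZStatMap, out_dir: str | Path, df: int | None = None,
              affine: np.ndarray | None = None) -> Path:
    """Write ``{group}_{contrast_id}_z.nii.gz`` (empties as 0) plus a
    JSON sidecar recording df and the empty-voxel dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    vol = np.nan_to_num(zmap.volume, nan=0.0).astype(np.float32)
    path = out / f"{zmap.group_label}_{zmap.contrast_id}_z.nii.gz"
    nib.save(nib.Nifti1Image(vol, affine), path)
    sidecar = {
        "contrast_id": zmap.contrast_id,
        "group_label": zmap.group_label,
        "df": df,
        "empty_value": 0.0,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def load_zmap(path: str | Path, mask: BrainMask) -> ZStatMap:
    """Read a Z map written by :func:`save_zmap`; voxels outside the
    mask become empty (in-mask zeros are kept as values)."""
    path = Path(path)
    img = nib.load(path)
    vol = np.asarray(img.get_fdata(), dtype=float)
    vol = np.where(mask.volume, vol, np.nan)
    stem = path.name
    for suffix in ("_z.nii.gz", "_z.nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    group, _, contrast = stem.partition("_")
    return ZStatMap(contrast_id=contrast, group_label=group, volume=vol)
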