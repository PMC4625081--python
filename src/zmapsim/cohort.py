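"""Synthetic multi-subject contrast-map cohorts.

Emulates the structure of a large task-fMRI cohort: a set of task
contrasts with smooth spatial effect templates (some pairs within a task
deliberately sharing part of their signal, like "0-back body" vs
"body"), subjects nested in families, and per-subject maps built from
the contrast template plus smooth family, subject and background noise
fields.  Also provides the family-constrained two-group subsampling used
to form independent groups A and B.

Within-group relatives are permitted; the constraint forbids relatedness
only *between* the two groups.  "Related" means sharing a ``family_id``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "ContrastSpec",
    "CohortConfig",
    "SubjectMap",
    "SamplingInfeasibleError",
    "build_contrast_specs",
    "make_subject_records",
    "simulate_subject_maps",
    "sample_unrelated_groups",
    "ellipsoid_mask",
    "write_cohort",
    "read_subject_table",
]

#: FWHM of a Gaussian = FWHM_TO_SIGMA * sigma
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One subject's identity: unique id plus family membership."""

    subject_id: str
    family_id: str


@dataclasses.dataclass
class ContrastSpec:
    """A task contrast and its ground-truth spatial effect template."""

    contrast_id: str
    task_id: str
    signal_template: np.ndarray
    overlap_group: str | None = None


@dataclasses.dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``group_size`` defaults to 46, the per-group sample size of the
    original two-group design; the default cohort holds 465 subjects.
    Noise standard deviations are in the same (arbitrary) effect units
    as ``effect_amplitude``; smoothing FWHM is in voxels so the grid
    geometry stays abstract.
    """

    n_subjects: int = 465
    n_families: int = 155
    n_tasks: int = 7
    contrasts_per_task: int | Sequence[int] = (3, 19, 3, 3, 3, 3, 13)
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    effect_amplitude: float = 1.4
    subject_noise_sd: float = 1.0
    family_noise_sd: float = 0.3
    background_shared_sd: float = 0.4
    smoothing_fwhm_vox: float = 3.0
    overlap_fraction: float = 0.8
    blobs_per_contrast: int = 6
    group_size: int = 46
    seed: int = 0

    def contrast_counts(self) -> list[int]:
        if isinstance(self.contrasts_per_task, int):
            counts = [self.contrasts_per_task] * self.n_tasks
        else:
            counts = list(self.contrasts_per_task)
        if len(counts) != self.n_tasks:
            raise ValueError(
                f"contrasts_per_task has {len(counts)} entries "
                f"for n_tasks={self.n_tasks}"
            )
        return counts

    def validate(self) -> None:
        if self.n_families > self.n_subjects:
            raise ValueError("n_families must not exceed n_subjects")
        if 2 * self.group_size > self.n_subjects:
            raise ValueError("group_size*2 must not exceed n_subjects")
        for name in ("subject_noise_sd", "family_noise_sd",
                     "background_shared_sd", "smoothing_fwhm_vox"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if min(self.grid_shape) < 8:
            raise ValueError(
                "grid too small to place contrast blobs (min dimension 8)"
            )
        self.contrast_counts()


@dataclasses.dataclass
class SubjectMap:
    """One subject's effect map for one contrast."""

    subject_id: str
    contrast_id: str
    volume: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0])
    )


class SamplingInfeasibleError(RuntimeError):
    """The cohort has too few unrelated subjects to fill both groups."""


def _gaussian_blob(shape: tuple[int, int, int], center: np.ndarray,
                   sigma: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _blob_separation(shape: tuple[int, int, int], n_blobs: int) -> float:
    """Minimum center-to-center distance between blobs of different
    contrasts.

    Contrasts from different tasks engage essentially distinct regions,
    so unrelated templates must not collide by chance — only contrasts
    in an overlap group share signal, by construction.  The separation
    targets a modest packing fraction of the placement region so
    rejection sampling terminates, capped at 5 voxels; below 2 voxels
    the grid cannot keep the requested blobs apart at all.
    """
    region = float(np.prod(np.asarray(shape) * 0.7))
    sep = 2.0 * (0.15 * region / n_blobs * 3.0 / (4.0 * np.pi)) ** (1 / 3)
    sep = min(sep, 5.0)
    if sep < 2.0:
        raise ValueError(
            f"grid {shape} too small to place {n_blobs} separated blobs"
        )
    return sep


def _draw_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n_blobs: int,
    placed: list[np.ndarray],
    min_sep: float,
    max_tries: int = 400,
) -> list[tuple[np.ndarray, float, float]]:
    """Blob parameters: (center, sigma, signed amplitude).

    Centers stay in the central 70% of the grid (inside the default
    ellipsoid mask) and at least ``min_sep`` voxels from every blob
    already placed for another contrast; roughly one blob in four is a
    deactivation.  Accepted centers are appended to ``placed``.
    """
    out = []
    lo = np.array(shape) * 0.15
    hi = np.array(shape) * 0.85
    for _ in range(n_blobs):
        for _try in range(max_tries):
            center = rng.uniform(lo, hi)
            if all(np.linalg.norm(center - c) >= min_sep for c in placed):
                break
        else:
            raise ValueError(
                f"grid {shape} too small to place blobs "
                f"{min_sep:.1f} voxels apart"
            )
        placed.append(center)
        sigma = rng.uniform(0.07, 0.10) * min(shape)
        amp = rng.uniform(0.7, 1.0)
        if rng.uniform() < 0.25:
            amp = -amp
        out.append((center, sigma, amp))
    return out


def _render(blobs, shape) -> np.ndarray:
    vol = np.zeros(shape)
    for center, sigma, amp in blobs:
        vol += amp * _gaussian_blob(shape, center, sigma)
    return vol


def build_contrast_specs(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[ContrastSpec]:
    """Create effect templates for every contrast of every task.

    Each template is a sum of smooth positive and negative Gaussian
    blobs.  Within every task that has at least two contrasts, the first
    two form an overlap group: they share ``overlap_fraction`` of their
    blobs exactly (same location, width and sign), so their supports
    overlap by at least that fraction — the synthetic analogue of
    redundant contrasts such as "0-back body" vs "body".

    Deterministic given ``config.seed`` when ``rng`` is not supplied.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    shape = tuple(config.grid_shape)
    nb = config.blobs_per_contrast
    n_shared = int(round(config.overlap_fraction * nb))
    counts = config.contrast_counts()
    # distinct blobs across the whole contrast set (shared ones counted once)
    n_distinct = sum(
        n_shared + 2 * (nb - n_shared) + (n - 2) * nb if n >= 2 else n * nb
        for n in counts
    )
    min_sep = _blob_separation(shape, max(n_distinct, 1))
    placed: list[np.ndarray] = []
    specs: list[ContrastSpec] = []
    for t_idx, n_con in enumerate(counts):
        task_id = f"task{t_idx:02d}"
        shared = (
            _draw_blobs(rng, shape, n_shared, placed, min_sep)
            if n_con >= 2 else []
        )
        for c_idx in range(n_con):
            cid = f"{task_id}_con{c_idx:02d}"
            in_overlap = n_con >= 2 and c_idx < 2
            if in_overlap:
                own = _draw_blobs(rng, shape, nb - n_shared, placed, min_sep)
                blobs = shared + own
                group = f"{task_id}_ovl"
            else:
                blobs = _draw_blobs(rng, shape, nb, placed, min_sep)
                group = None
            specs.append(
                ContrastSpec(
                    contrast_id=cid,
                    task_id=task_id,
                    signal_template=_render(blobs, shape),
                    overlap_group=group,
                )
            )
    return specs


def make_subject_records(config: CohortConfig) -> list[SubjectRecord]:
    """Assign subjects to families round-robin."""
    return [
        SubjectRecord(
            subject_id=f"sub{i:04d}",
            family_id=f"fam{i % config.n_families:04d}",
        )
        for i in range(config.n_subjects)
    ]


def _smooth_field(rng: np.random.Generator, shape, fwhm_vox: float,
                  sd: float) -> np.ndarray:
    """Smoothed Gaussian field rescaled to the requested grid-wide sd.

    The white-noise draw is consumed even when sd == 0 so that toggling
    a noise term off does not shift every later draw.
    """
    white = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    if fwhm_vox > 0:
        field = gaussian_filter(white, fwhm_vox / _FWHM_TO_SIGMA)
    else:
        field = white
    scale = field.std()
    return field * (sd / scale) if scale > 0 else field


def simulate_subject_maps(
    specs: Sequence[ContrastSpec],
    records: Sequence[SubjectRecord],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[SubjectMap]:
    """Simulate per-subject contrast maps.

    Generative model, per subject s (family f) and contrast c::

        volume = effect_amplitude * template_c
               + family_field(f, c)        # sd family_noise_sd
               + subject_noise(s, c)       # sd subject_noise_sd
               + background_field(s)       # sd background_shared_sd

    All noise terms are smoothed white noise (FWHM ``smoothing_fwhm_vox``
    voxels).  The background field is drawn once per subject and shared
    across all of that subject's contrasts; because groups A and B are
    disjoint, it survives group averaging as structured noise that is
    independent between groups and between different contrasts of the
    A-vs-B comparison, so near-zero values behave as noise rather than
    shared signal.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    shape = tuple(config.grid_shape)
    fwhm = config.smoothing_fwhm_vox

    background = {
        r.subject_id: _smooth_field(rng, shape, fwhm,
                                    config.background_shared_sd)
        for r in records
    }
    family_ids = sorted({r.family_id for r in records})

    maps: list[SubjectMap] = []
    for spec in specs:
        signal = config.effect_amplitude * spec.signal_template
        family_field = {
            fid: _smooth_field(rng, shape, fwhm, config.family_noise_sd)
            for fid in family_ids
        }
        for rec in records:
            noise = _smooth_field(rng, shape, fwhm, config.subject_noise_sd)
            vol = (signal + family_field[rec.family_id] + noise
                   + background[rec.subject_id])
            maps.append(
                SubjectMap(
                    subject_id=rec.subject_id,
                    contrast_id=spec.contrast_id,
                    volume=vol,
                )
            )
    return maps


def sample_unrelated_groups(
    records: Sequence[SubjectRecord],
    group_size: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[list[str], list[str]]:
    """Draw two disjoint groups with no family shared between them.

    Group A is a uniform draw without replacement; candidates for group B
    are then drawn from the remainder in random order and admitted only
    if their family does not appear in A.  If B cannot be filled the
    whole draw (including A) is retried, up to ``max_attempts`` times.
    """
    if not records:
        raise ValueError("records is empty")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if 2 * group_size > len(records):
        raise SamplingInfeasibleError(
            f"need {2 * group_size} subjects, have {len(records)}"
        )
    idx = np.arange(len(records))
    for _ in range(max_attempts):
        a_idx = rng.choice(idx, size=group_size, replace=False)
        a_fams = {records[i].family_id for i in a_idx}
        remainder = np.setdiff1d(idx, a_idx)
        rng.shuffle(remainder)
        b: list[str] = []
        for i in remainder:
            if records[i].family_id not in a_fams:
                b.append(records[i].subject_id)
                if len(b) == group_size:
                    return [records[i].subject_id for i in a_idx], b
    raise SamplingInfeasibleError(
        f"could not assemble two family-disjoint groups of {group_size} "
        f"in {max_attempts} attempts"
    )


def ellipsoid_mask(grid_shape: Sequence[int],
                   radius_fraction: float = 0.42) -> np.ndarray:
    """Binary ellipsoid inscribed in the grid (the default brain mask)."""
    shape = tuple(grid_shape)
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * radius_fraction
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semi))
    return d2 <= 1.0


# ---------------------------------------------------------------------------
# disk formats: NIfTI volumes, TSV subject table, JSON contrast manifest

def write_cohort(
    out_dir: str | Path,
    specs: Sequence[ContrastSpec],
    records: Sequence[SubjectRecord],
    maps: Sequence[SubjectMap],
    mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> None:
    """Write subject maps ({subject}_{contrast}.nii.gz), the subject TSV,
    the contrast manifest JSON and the brain mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    with open(out / "subjects.tsv", "w") as fh:
        fh.write("subject_id\tfamily_id\n")
        for r in records:
            fh.write(f"{r.subject_id}\t{r.family_id}\n")
    manifest = [
        {"contrast_id": s.contrast_id, "task_id": s.task_id,
         "overlap_group": s.overlap_group}
        for s in specs
    ]
    (out / "contrasts.json").write_text(json.dumps(manifest, indent=2))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine),
             out / "brain_mask.nii.gz")
    for m in maps:
        img = nib.Nifti1Image(m.volume.astype(np.float32), affine)
        nib.save(img, out / f"{m.subject_id}_{m.contrast_id}.nii.gz")
    logger.info("wrote cohort of %d maps to %s", len(maps), out)


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a two-column TSV with header subject_id<TAB>family_id."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subject_id", "family_id"]:
            raise ValueError(f"unexpected subject table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            sid, fid = line.rstrip("\n").split("\t")[:2]
            records.append(SubjectRecord(subject_id=sid, family_id=fid))
    if len({r.subject_id for r in records}) != len(records):
        raise ValueError("duplicate subject_id in subject table")
    return records
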