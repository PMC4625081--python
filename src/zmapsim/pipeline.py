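"""End-to-end experiment: simulate a cohort, repeatedly draw two
family-disjoint groups, build group Z maps per contrast, sweep
thresholds/directions/strategies/metrics over the full query-vs-target
score matrix, and evaluate classification accuracy.

Outputs are plain CSV/JSON files; every row carries its full condition
key so each file is self-describing.  Rerunning with the same config
and seed reproduces the numeric content byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .classify import NO_PREDICTION, ScoreMatrix, aggregate, evaluate_subsample
from .cohort import (
    CohortConfig,
    ContrastSpec,
    SubjectMap,
    build_contrast_specs,
    ellipsoid_mask,
    make_subject_records,
    sample_unrelated_groups,
    simulate_subject_maps,
)
from .groupstats import BrainMask, ZStatMap, one_sample_t, t_to_z
from .similarity import METRICS, STRATEGIES, compare
from .thresholding import ThresholdSpec, apply_threshold

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "load_config", "build_group_zmaps"]

_DIRECTIONS = ("both", "positive")

_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}
_TOP_KEYS = {
    "cohort", "thresholds", "directions", "strategies", "metrics",
    "n_subsamples", "out_dir", "seed", "log_level",
}


@dataclasses.dataclass
class ExperimentConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    thresholds: Sequence[float] = tuple(float(t) for t in range(14))
    directions: Sequence[str] = _DIRECTIONS
    strategies: Sequence[str] = STRATEGIES
    metrics: Sequence[str] = METRICS
    n_subsamples: int = 500
    out_dir: str = "zmapsim_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("thresholds", "directions", "strategies", "metrics"):
            if not list(getattr(self, name)):
                raise ValueError(f"{name} must be nonempty")
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be >= 0")
        bad = set(self.directions) - set(_DIRECTIONS)
        if bad:
            raise ValueError(f"unknown directions: {sorted(bad)}")
        bad = set(self.strategies) - set(STRATEGIES)
        if bad:
            raise ValueError(f"unknown strategies: {sorted(bad)}")
        bad = set(self.metrics) - set(METRICS)
        if bad:
            raise ValueError(f"unknown metrics: {sorted(bad)}")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML experiment config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cohort_raw = raw.pop("cohort", {}) or {}
    unknown = set(cohort_raw) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    if "grid_shape" in cohort_raw:
        cohort_raw["grid_shape"] = tuple(cohort_raw["grid_shape"])
    if "contrasts_per_task" in cohort_raw and \
            not isinstance(cohort_raw["contrasts_per_task"], int):
        cohort_raw["contrasts_per_task"] = tuple(
            cohort_raw["contrasts_per_task"]
        )
    config = ExperimentConfig(cohort=CohortConfig(**cohort_raw), **raw)
    config.validate()
    return config


@dataclasses.dataclass
class ExperimentResult:
    scores: pd.DataFrame
    accuracy: pd.DataFrame
    per_contrast: pd.DataFrame
    confusions: dict[tuple, np.ndarray]
    contrast_ids: list[str]
    out_dir: Path | None


def build_group_zmaps(
    subject_maps: dict[tuple[str, str], SubjectMap],
    specs: Sequence[ContrastSpec],
    group_ids: Sequence[str],
    group_label: str,
    mask: BrainMask,
) -> dict[str, ZStatMap]:
    """One-sample t then Z per contrast for one subject group."""
    zmaps = {}
    for spec in specs:
        maps = [subject_maps[sid, spec.contrast_id] for sid in group_ids]
        tmap = one_sample_t(maps, mask)
        tmap.group_label = group_label
        zmaps[spec.contrast_id] = t_to_z(tmap)
    return zmaps


def _condition_iter(config: ExperimentConfig):
    for threshold in config.thresholds:
        for direction in config.directions:
            for strategy in config.strategies:
                for metric in config.metrics:
                    yield float(threshold), direction, strategy, metric


def run_experiment(config: ExperimentConfig,
                   write: bool = True) -> ExperimentResult:
    """Run the full subsample -> group maps -> sweep -> evaluate loop.

    Group Z maps are computed once per subsample and thresholded lazily
    per condition (with caching); the query side always stays
    unthresholded.  RNG substreams are derived from ``config.seed`` per
    stage and subsample index, so results are reproducible regardless
    of execution order.
    """
    config.validate()
    cohort = config.cohort
    logger.info(
        "experiment: %d contrasts x %d subsamples x %d thresholds x "
        "%d directions x %d strategies x %d metrics",
        sum(cohort.contrast_counts()), config.n_subsamples,
        len(list(config.thresholds)), len(list(config.directions)),
        len(list(config.strategies)), len(list(config.metrics)),
    )

    specs = build_contrast_specs(cohort, substream(config.seed, 0, 0))
    records = make_subject_records(cohort)
    maps = simulate_subject_maps(specs, records, cohort,
                                 substream(config.seed, 0, 1))
    subject_maps = {(m.subject_id, m.contrast_id): m for m in maps}
    mask = BrainMask(ellipsoid_mask(cohort.grid_shape))
    contrast_ids = [s.contrast_id for s in specs]
    n_con = len(contrast_ids)

    score_rows: list[tuple] = []
    # predictions[(threshold, direction, strategy, metric)] -> list of rows
    predictions: dict[tuple, list[np.ndarray]] = {
        cond: [] for cond in _condition_iter(config)
    }

    for sub_idx in range(config.n_subsamples):
        rng = substream(config.seed, 1, sub_idx)
        ids_a, ids_b = sample_unrelated_groups(records, cohort.group_size,
                                               rng)
        zmaps_a = build_group_zmaps(subject_maps, specs, ids_a, "A", mask)
        zmaps_b = build_group_zmaps(subject_maps, specs, ids_b, "B", mask)

        thresh_cache: dict[tuple, dict[str, ZStatMap]] = {}
        for cond in _condition_iter(config):
            threshold, direction, strategy, metric = cond
            key = (threshold, direction)
            if key not in thresh_cache:
                spec_t = ThresholdSpec(level=threshold, direction=direction)
                thresh_cache[key] = {
                    cid: apply_threshold(zmaps_b[cid], spec_t)
                    for cid in contrast_ids
                }
            targets = thresh_cache[key]
            values = np.empty((n_con, n_con))
            for i, qid in enumerate(contrast_ids):
                for j, tid in enumerate(contrast_ids):
                    score = compare(zmaps_a[qid], targets[tid], strategy,
                                    metric, mask, direction)
                    values[i, j] = score.value
                    score_rows.append(
                        (sub_idx, threshold, direction, strategy, metric,
                         qid, tid, score.value, score.n_voxels)
                    )
            matrix = ScoreMatrix(
                values=values,
                contrast_ids=contrast_ids,
                condition={
                    "threshold": threshold, "direction": direction,
                    "strategy": strategy, "metric": metric,
                },
            )
            preds, _, _ = evaluate_subsample(matrix)
            predictions[cond].append(preds)
        logger.info("subsample %d/%d done", sub_idx + 1, config.n_subsamples)

    scores = pd.DataFrame(
        score_rows,
        columns=["subsample", "threshold", "direction", "strategy",
                 "metric", "query_contrast", "target_contrast", "score",
                 "n_voxels"],
    )

    acc_rows, per_con_rows, confusions = [], [], {}
    for cond, preds in predictions.items():
        threshold, direction, strategy, metric = cond
        condition = {"threshold": threshold, "direction": direction,
                     "strategy": strategy, "metric": metric}
        summary, confusion = aggregate(np.array(preds), contrast_ids,
                                       condition)
        acc_rows.append(
            (threshold, direction, strategy, metric, summary.overall_mean,
             summary.ci_low, summary.ci_high, summary.n_subsamples)
        )
        for k, cid in enumerate(contrast_ids):
            per_con_rows.append(
                (threshold, direction, strategy, metric, cid,
                 summary.per_contrast_mean[k], summary.per_contrast_sd[k])
            )
        confusions[cond] = confusion.counts
    accuracy = pd.DataFrame(
        acc_rows,
        columns=["threshold", "direction", "strategy", "metric",
                 "mean_accuracy", "ci_low", "ci_high", "n_subsamples"],
    )
    per_contrast = pd.DataFrame(
        per_con_rows,
        columns=["threshold", "direction", "strategy", "metric",
                 "contrast_id", "mean", "sd"],
    )

    out_dir = None
    if write:
        out_dir = _write_bundle(config, scores, accuracy, per_contrast,
                                confusions, contrast_ids)
    return ExperimentResult(
        scores=scores, accuracy=accuracy, per_contrast=per_contrast,
        confusions=confusions, contrast_ids=contrast_ids, out_dir=out_dir,
    )


def _write_bundle(config, scores, accuracy, per_contrast, confusions,
                  contrast_ids) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "complete": False,
        "config": _config_to_dict(config),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))

    scores.to_csv(out / "scores.csv", index=False)
    accuracy.to_csv(out / "accuracy_summary.csv", index=False)
    per_contrast.to_csv(out / "per_contrast_accuracy.csv", index=False)
    for (threshold, direction, strategy, metric), counts in \
            confusions.items():
        name = (f"confusion_T{threshold:g}_{direction}_{strategy}_"
                f"{metric}.csv")
        df = pd.DataFrame(counts, index=contrast_ids,
                          columns=contrast_ids + ["no_prediction"])
        df.to_csv(out / name, index_label="true_contrast")

    summary_json = {
        "accuracy": accuracy.to_dict(orient="records"),
        "per_contrast": per_contrast.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2))
    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("wrote result bundle to %s", out)
    return out


def _config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds"] = [float(t) for t in d["thresholds"]]
    for key in ("directions", "strategies", "metrics"):
        d[key] = list(d[key])
    d["cohort"]["grid_shape"] = list(d["cohort"]["grid_shape"])
    if not isinstance(d["cohort"]["contrasts_per_task"], int):
        d["cohort"]["contrasts_per_task"] = list(
            d["cohort"]["contrasts_per_task"]
        )
    return d
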