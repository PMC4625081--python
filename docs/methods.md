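# Methods

## Overview

`zmapsim` measures how thresholding a statistical brain map changes its
correlation-based similarity to other maps, operationalized as a
retrieval task: an unthresholded group Z map for one task contrast
(query) is scored against thresholded group Z maps for every contrast
from an independent subject group (targets), and classification is
correct when the matching contrast wins. Because suitable multi-task,
family-structured subject cohorts are restricted-access, the package
generates synthetic cohorts whose group maps reproduce the structural
features the analysis depends on; everything downstream of the
generator (group statistics, thresholding, scoring, evaluation) is the
analysis proper and applies unchanged to real NIfTI data.

## Synthetic cohort model

Each contrast *c* has a ground-truth effect template: a sum of
`blobs_per_contrast` smooth Gaussian blobs (width 7–10% of the grid's
smallest dimension, peak amplitude 0.7–1.0 in arbitrary effect units,
~25% of blobs negative to give deactivations). Blob centers of
*different* contrasts keep a minimum separation (derived from a target
packing fraction of the placement region, capped at 5 voxels): distinct
task contrasts engage essentially distinct regions, and without the
separation chance blob collisions dominate the confusion structure,
which real between-task contrasts do not show. Within every task with
at least two contrasts, the first two form an *overlap group* sharing
`overlap_fraction` (default 0.8) of their blobs verbatim — the analogue
of near-redundant contrasts such as a sub-condition and its
generalization, which are the contrasts real cohorts confuse. A
configuration whose grid cannot host the requested blobs at the minimum
viable separation is rejected as an error.

The map of subject *s* (family *f*) for contrast *c* is

    volume = effect_amplitude · template_c
           + family_field(f, c)     (sd family_noise_sd, default 0.3)
           + subject_noise(s, c)    (sd subject_noise_sd, default 1.0)
           + background_field(s)    (sd background_shared_sd, default 0.4)

with every noise term a Gaussian-smoothed white field (FWHM
`smoothing_fwhm_vox`, default 3 voxels; fields rescaled to the stated
grid-wide sd after smoothing). The family field is drawn once per
family per contrast and shared by its members, which is precisely the
between-group dependence the family-disjoint sampling constraint
protects against. The background field is drawn once per subject and
shared across all of that subject's contrasts; since groups A and B are
subject-disjoint, it survives group averaging as smooth structured
noise that is independent between any query and any target — this is
what makes near-zero Z values behave as noise in the comparisons rather
than as shared signal. Deliberately *not* modeled: acquisition or
preprocessing artifacts, anatomical variability, non-Gaussian noise,
degrees of kinship beyond shared family membership, realistic brain
geometry (the default mask is an ellipsoid), or between-task amplitude
differences. Passing tests therefore show that the analysis machinery
behaves correctly under the stated generative assumptions, not that any
particular accuracy value transfers to real data.

`effect_amplitude` (default 1.4) sets the per-voxel effect-to-noise
ratio. At the default group size used in the scaled experiments
(n = 12) it puts peak |Z| around 5.5, just under the top of the scaled
0–6 threshold sweep — the sweep is meant to span the maps' full Z
range, reaching total extinction at its top. Template energy (blob
count × blob volume), not peak height, controls the same-contrast
correlation, because the t→Z transform pins the noise variance of a
group map at 1; the default of 6 blobs per contrast gives same-contrast
Pearson r ≈ 0.4–0.5 over the mask and near-ceiling retrieval at low
thresholds, the regime of interest.

## Group subsampling

Group A is a uniform draw of `group_size` subjects without replacement;
candidates for group B are drawn from the remainder in random order and
admitted only if they share no family with A. Within-group relatives
are allowed — the constraint is only between groups. If B cannot be
filled, the entire draw (including A) is retried, up to `max_attempts`
times before a sampling-infeasible error; the retry makes degenerate
cohorts (e.g. two families) land on the only admissible splits instead
of failing stochastically. Subsamples are redrawn independently per
iteration; the same subject may appear in different iterations.

## Group statistics

Per masked voxel, t = x̄/(s/√n) with the unbiased (n−1) standard
deviation and df = n−1. Zero-variance voxels become empty (NaN) and are
counted in a log summary — infinities would poison every downstream
correlation, and empties are already first-class. The t-test is
parametric; permutation machinery adds nothing here because only the
t-statistic image itself is consumed.

t→Z preserves tail precision by computing the upper-tail probability of
|t| as a log (`scipy.stats.t.logsf`) and inverting the normal CDF
directly from the log probability (`scipy.special.ndtri_exp`); the sign
of t is applied afterwards, making the transform exactly antisymmetric.
Where even log-sf underflows (|t| beyond ~10⁶ at moderate df) the
power-law tail asymptotic sf(t) ≈ C(df)·t^(−df) takes over, so Z is
finite for every finite t. Empty voxels propagate as NaN. NIfTI export
writes 0 at empty voxels and records df in a JSON sidecar; the brain
mask disambiguates written zeros on load.

## Thresholding

Two-sided thresholding keeps values strictly above +T or strictly below
−T ("strictly": boundary values are removed; the convention matters
only on a measure-zero set). T = 0 two-sided is the identity, exact
zeros included. Positive-only keeps values strictly above +T at every
level — at T = 0 it removes all negatives and exact zeros, a deliberate
and documented asymmetry: positive-only analysis means eliminating
negative values, not merely cutting at a level. Re-thresholding is
permitted only when it composes (same direction, or two-sided followed
by positive-only, at a level no lower than the existing one).

## Similarity and classification

The query is always unthresholded: retrieval is asymmetric by design
(a researcher queries with their full map against a database of
possibly-thresholded maps; thresholded-vs-thresholded comparison needs
different machinery and is out of scope). Under positive-only
directionality the positive filter is applied to *both* images,
including the query — directionality is treated as a property of the
analysis, not of one image; the alternative (filtering only the
target) is a plausible reading and is available by passing a
pre-filtered query with `direction="both"`.

CCA restricts to mask voxels non-zero and non-NaN in both images; SVI
uses every mask voxel with empties imputed to 0 (the mask, not the
rectangular grid, is the comparison universe). Scores are Pearson or
Spearman (average ranks on ties) via scipy; a pair with fewer than
three voxels, no survivors, or a zero-variance vector is not comparable
and serializes as NaN rather than raising, so a full score matrix
always exists. Prediction is the maximum |score| per row; NaN ranks
below everything; an all-NaN row is a no-prediction, scored incorrect
and tallied in a dedicated confusion column so confusion rows always
sum to the subsample count. Ties on |score| break to the lowest column
index and are logged — ties are measure-zero on real data and the rule
exists purely for determinism.

Accuracy per condition is the mean over subsamples, with a 95% interval
from the normal approximation mean ± 1.96·sd/√n over subsample
accuracies (adequate for the accuracy ranges and subsample counts used;
a single subsample degenerates to the mean with a warning). Per-contrast
means/sds are over the 0/1 correctness indicators.

## Pipeline and reproducibility

`run_experiment` simulates the cohort once, then per subsample draws
groups, builds one t and Z map per group×contrast, thresholds targets
lazily per condition with caching, scores all query×target pairs, and
evaluates. Every RNG consumer gets a substream
`SeedSequence([seed, stage, index])` (stage 0 = cohort, stage 1 =
subsample draws), so serial or any parallel schedule over subsamples is
bit-identical; the `--threads` flag is accepted for interface stability
but execution is currently serial. All outputs are long-format CSV/JSON
with the full condition key on every row, plus a manifest with config,
seed, version and a completeness flag.

## Problem sizes

The scaled experiment used by the test suite and by
`scripts/acceptance.py` — 12 contrasts (one overlap pair), 24³ grid
(~6,900-voxel ellipsoid mask), groups of 12 from 48 subjects in 16
families, 20 subsamples, thresholds 0–6 — is the package's chosen
desk-scale configuration: it reproduces the qualitative regime
(near-ceiling accuracy at low thresholds, monotone degradation,
extinction at the sweep top, confusion concentrated on the redundant
pair) in about half a minute. The full-size configuration (47 contrasts
over 7 tasks, 465 subjects, groups of 46, 500 subsamples, thresholds
0–13, all four condition axes) validates and runs with the same code
path, only longer.

## Known limitations

* Correlations are computed over voxels that are spatially correlated
  (smoothing); reported scores are descriptive, and no p-values are
  attached to them — the classification framing avoids needing any.
* The synthetic generator's noise is stationary and Gaussian; real
  maps have spatially varying noise, physiological structure, and
  registration error.
* Survival fractions depend on the generator's Z-value distribution
  and should not be read as predictions for any real dataset.
* The 95% intervals treat subsample accuracies as independent, but
  subsamples share subjects; the intervals are mildly anti-conservative.
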