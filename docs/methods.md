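# Methods

This note documents the models, conventions and design choices behind
`neurodist`: what each stage computes, why the defaults are what they are,
and what the synthetic-data results do and do not establish about real data.

## 1. The distance-to-bound model

A linear decoder trained on multivoxel patterns defines a hyperplane
`{x : w·x + b = 0}`. For a held-out pattern, the decision value `w·x + b` is
a signed, unitless distance to that hyperplane; its absolute value is taken
as a proxy for the strength of the category evidence the pattern carries.
The behavioral prediction is a monotone link between this distance and
reaction time: negative (far = fast) when the task requires the decoded
category distinction, positive (far = slow) when the category signal
interferes with an orthogonal task. The pipeline estimates this link as the
Pearson correlation between per-scene distances and per-scene mean RTs,
per subject and ROI/searchlight, and tests it at the group level.

## 2. First-level estimation

- **Design matrices.** One boxcar regressor per scene (onsets/durations from
  the event table), convolved with an HRF on a micro-time grid of TR/16 and
  sampled at scan times; nuisance regressors are consumed as given columns;
  a trailing intercept is always appended. Micro-time convolution keeps
  onset-discretization error below the sampling grid.
- **HRF selection.** The GLM is refit once per member of an HRF library
  (default: 20 double-gamma kernels crossing 10 peak delays in 4–8 s with
  two undershoot ratios, 1/6 and 1/3, peak-normalized). Per voxel, the betas
  from the member with the minimum **mean squared** residual are retained.
  Ties break toward the lowest library index (deterministic). "Mean
  residual" is implemented as mean squared residual; mean absolute residual
  would select identically for nested noise-free cases but is not offered.
  Selection uses no condition-specific information, so it introduces no
  positive decoding bias.
- **ROIs.** ROI = atlas mask ∩ {one-sided t-map p < 1e−4 at the stated df}.
  One-sided because localizer contrasts are directional. Voxels surviving in
  more than one ROI are removed from all; an ROI left empty warns rather
  than errors, and downstream decoding flags it missing instead of skipping.

## 3. Decoding conventions

- **Pseudo-betas.** Per scene and repeat: 4 random run betas → 1 test
  pseudo-beta (mean); remaining runs shuffled, grouped in pairs, averaged →
  train pseudo-betas; leftovers beyond a full pair are dropped so all train
  pseudo-betas share the same averaging count (homogeneous noise). With 10
  runs this gives 3 train pseudo-betas per scene, with 8 runs 2.
- **Classifier.** Soft-margin linear SVM with fixed C = 1 and no per-fold
  hyperparameter search (seed-reproducible; C configurable). Voxels are
  z-scored with train-set mean/sd applied unchanged to the test set (sd
  floored at 1e−12). Decision-value sign convention: positive = the
  first-listed class (man-made; the target category).
- **Basic-level scheme.** Positives: all k exemplars of the target.
  Negatives: k exemplars sampled per repeat from the sibling categories of
  the same superordinate, split as evenly as possible (5+5 in the 2×3×10
  design). Accuracy is reported on targets + sampled distractors (the
  default; targets-only is also computed), keeping chance at 0.5.
- **Repeats.** Split, grouping and distractor sampling are re-randomized
  each repeat (default 100); accuracies average over repeats.
- **Chance levels.** 0.5 for both schemes (balanced designs by
  construction).

## 4. Distances, RTs, reliability

- Distance = mean over repeats of |decision value| (the alternative,
  |mean decision value|, is behind `abs_of_mean=True`; they differ when the
  sign flips across repeats). Basic-level distances come from each scene's
  own target decoder and are concatenated to cover all scenes.
- RT aggregation is a two-stage mean: within subject over correct trials,
  then unweighted across subjects; a subject with no correct trial for a
  scene drops out of that scene's mean; a scene with no correct trial at
  all is an error listing the scene.
- Joint reliability: split-half r per measure (distances: odd vs even runs,
  decoded separately within each half with a reduced split; RTs: random
  subject halves averaged over 100 splits), Spearman–Brown corrected, then
  √(product). Negative split-half correlations are *not* truncated before
  the correction; a negative product makes the ceiling undefined and is
  reported as missing (`None`), never as NaN propagation. For display next
  to a negative distance–RT correlation the ceiling is sign-inverted.

## 5. Searchlight

Neighborhoods are Euclidean balls (radius in mm when voxel sizes are given,
voxels otherwise; default 4 voxels — an assumption, configurable)
intersected with the mask; every neighborhood contains its center, and
neighborhoods below `min_voxels` (default 2) are flagged invalid.
Each center draws an RNG substream keyed by (master seed, "searchlight",
center index), so maps are independent of execution order and the value at
any center is bit-identical to running the ROI pipeline on that
neighborhood mask with the same key — the property the equivalence tests
assert. Spatial normalization to a template is out of scope; group analyses
assume maps already share a grid (true by construction for synthetic data).

## 6. Commonality analysis

Model features are PCA-reduced per layer: components fitted on the centered
training pool only, applied unchanged to the experimental scenes; layers
whose dimensionality is already ≤ `n_components` pass through unreduced.
Requested components beyond the achievable rank clip with a warning.
Model distances are |decision values| of the experimental scenes under an
SVM trained on the reduced pool (basic-level: all target-category pool
images vs half of each distractor category, resampled per repeat).

Commonality partitions the RT variance: three OLS fits (y on A, on B, on
A+B; intercept included, R² unadjusted), then
`C(AB) = R²_y.A + R²_y.B − R²_y.AB`, with `R²_y.A` reported as the upper
limit. OLS uses a minimum-norm least-squares solve, so exact collinearity
of A and B never crashes and leaves R²_y.AB well defined. Negative C
(suppression) is reported, not clipped. The group layer profile is the
arg-max of the subject-mean C per layer, 1-based, ties broken toward the
lower index and flagged.

## 7. Group inference

- **Sign permutation.** Subject statistics are centered by the chance level
  (0.5 for accuracy, 0 for correlations and R²), signs flipped per subject,
  and the observed group mean ranked in the permutation distribution. When
  2ⁿ ≤ n_perm all sign patterns are enumerated and the p-value is exact;
  otherwise p = (1 + #extreme)/(1 + n_perm), which includes the identity
  permutation so p > 0 always. Comparisons use a 1e−12 tie tolerance.
  Default n_perm = 10,000. One-sided for accuracies and R², two-sided for
  distance–RT correlations.
- **FDR.** Benjamini–Hochberg step-up without dependency correction
  (delegated to `statsmodels.multipletests`, verified in tests against a
  brute-force step-up oracle), intended for small families (ROIs, layers).
- **Cluster-extent correction.** Per permutation, one sign flip per subject
  is applied to the subject's whole map, preserving spatial structure.
  Voxelwise permutation p-maps (rank of each permutation's map within the
  full permutation distribution, per voxel) are thresholded at p < 0.001;
  suprathreshold voxels are clustered by 6-connectivity (faces; 18/26
  configurable); each observed cluster's p is the rank of its size in the
  maximum-cluster-size null (identity included); clusters with p < 0.05 are
  significant. Two-sided inference runs the two tails as separate analyses
  and unions the significant masks. No suprathreshold voxels is a valid,
  empty result. Note the rank-based p is quantized at 1/n_perm, so the
  voxel threshold must satisfy voxel_p > 1/n_perm to be non-degenerate;
  calibration studies at n_perm = 200 therefore use voxel_p = 0.01 while
  the analysis default stays 0.001 at n_perm = 10,000.
- **Bootstrap peak CI.** Subjects resampled with replacement (default
  100,000 draws, chunked to bound memory), subject-mean curve per draw,
  arg-max layer (lowest index on ties); the CI is the 2.5/97.5 percentile
  pair taken outward (floor/ceil) so both bounds are layer indices.
- **Overlap.** 100·|A∩B|/|A| and /|B|; an empty denominator set yields 0.

## 8. The synthetic generator

Voxel pattern of scene *s* in run *r*:

```
beta[s, r] = (super_effect/2)·sign(s)·u_super + basic_effect·u_basic[b(s)]
             + e_s + eps[s, r]
```

with `u_super` a random unit axis, per-category unit axes `u_basic`
orthogonalized against it, a fixed per-scene exemplar component `e_s`, and
i.i.d. run noise `eps ~ N(0, run_noise_sd²)`. Under this linear-Gaussian
model with isotropic noise a linear hyperplane is Bayes-optimal, and the
true signed distance of a scene is the projection of its noiseless pattern
onto `u_super`.

The exemplar component has two parts with distinct roles:

- `exemplar_sd` — isotropic scatter. Its projection onto `u_super` moves
  the true distance slightly, but the bulk is orthogonal and acts as
  structured noise for the distance–RT relation (a max-margin hyperplane
  partially overfits it in high dimensions).
- `exemplar_axis_sd` — scatter specifically along the boundary axis, the
  component that genuinely spreads scenes in "typicality". The axis offsets
  are drawn **antithetically** between the two superordinate classes
  (mirrored), so the realized finite scene set is symmetric about the
  planted boundary and the boundary at 0 is exactly optimal for it — this
  makes the stored ground-truth distances exact rather than merely
  population-level, and in the vanishing-noise limit the decoded distances
  become exactly affine in the true ones (the noiseless recovery tests
  reach r = ±1.0 to machine precision).

RTs: `rt = intercept + subject offset + task_sign·slope·distance + noise`,
truncated at a 0.15 s floor (truncation, not resampling, preserves seed
determinism); each trial is correct with probability `accuracy_rate`.
Defaults: intercept 0.7 s, slope 0.15 s per distance unit, trial noise
0.15 s, 24 trials/scene, accuracy 0.8, 30 behavioral subjects — RT
magnitudes and correct-trial counts in the range typical of speeded scene
categorization.

Model features: per layer, a category axis and orthogonal basic-category
axes scaled by a Gaussian-bump complexity profile over layers (default
width 0.8, peak value 1) plus i.i.d. feature noise (default sd 0.3); the
experimental scenes' category component is scaled by an optional per-scene
`scene_signal` (typically the signed true distance from the beta
generator), which is what couples model distances to RTs and neural
distances at the scene level and makes the commonality peak recoverable.
The profile/noise defaults were fixed during generator design so that the
planted peak is cleanly identifiable by the full pipeline.

Volumetric datasets plant axis-aligned box clusters inside a brain mask;
only in-cluster voxels carry the (scene-scalar × random weight) category
signal, so searchlight and cluster-correction recovery have exact ground
truth. `noise_seed` decouples run noise from the scene-level structure:
datasets sharing `seed` but differing in `noise_seed` emulate multiple
subjects measuring the same underlying representation — the multi-subject
regime the pipeline's group stages are exercised on.

**What the generator does not emulate:** voxelwise noise covariance and
spatial autocorrelation (noise is i.i.d.; real beta noise is smooth and
structured), BOLD physiology beyond HRF convolution, trial-order and
adaptation effects, behavioral lapses/speed–accuracy trade-offs, and
between-subject anatomical variability. Passing tests therefore establish
the *estimators'* correctness and calibration under the stated model, not
effect sizes or power on real fMRI data.

## 9. Determinism and problem sizes

All randomness flows from a master seed through `SeedSequence` spawn keys
structured as (subject, ROI, scheme, target, repeat, searchlight center, …),
so results are independent of iteration order and parallelism, and two runs
of one config produce byte-identical TSVs (fixed `%.10g` float format,
LF endings). The run manifest records config hash, package version, output
checksums and per-stage wall time; a rerun whose outputs all verify against
the manifest is skipped.

The test suite and `scripts/acceptance.py` run the calibration/recovery
studies at reduced scale, chosen as the smallest sizes at which each
property is statistically decisive: 24–60 scenes, 8–10 runs, 24–100 voxels,
2–8 decode repeats, 200–500 permutations, 12³ null volumes (500 datasets),
50–100 simulated studies per recovery rate. The analysis defaults
(100 repeats, 10,000 permutations, 100,000 bootstrap draws) remain the
package's production settings.

## 10. Known limitations

- The SVM hyperplane is estimated per repeat without hyperparameter search;
  C materially off-scale for a dataset will shrink decision-value spread
  (distances remain rank-informative).
- Split-half distance reliability uses odd/even runs with a reduced split
  inside each half, so it is not identical in SNR to the full-data split.
- The cluster-correction p-values are quantized at 1/n_perm; with few
  subjects, sampled sign patterns can duplicate the identity and create
  exact rank ties at the voxel threshold (correct but conservative).
- `first_level` starts at time series: no motion correction, slice timing,
  smoothing or normalization, and no aCompCor computation (nuisance
  regressors are consumed as given).
- Real model features enter through the on-disk feature-matrix interface;
  no network inference is performed in core.
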