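# Methods

This note documents the statistical model, the numerical choices, and
the synthetic-data conditions the package is validated under.

## Representational model

For a stimulus set of `n` images, all computation happens on the
`n(n−1)/2` unordered image pairs; the canonical vectorization is the
row-major upper triangle with `i < j` (identical to scipy's condensed
`squareform` order). Three RDM constructors are provided:

* `rdm_from_dimension` — squared difference of per-image values on one
  model dimension. For binary dimensions the entries are exactly 0/1.
* `rdm_correlation_distance` — `1 − r` between per-image response rows,
  Spearman (average ranks for ties) for network activations, Pearson
  for measured patterns. A zero-variance row has no defined correlation
  and is an error naming the image; callers must screen rectified
  activations rather than rely on silent NaN handling.
* `weighted_sum_rdms` — entrywise nonnegative combination. The algebraic
  identity that justifies fitting in RDM space: scaling dimension `d` by
  `w_d` before computing a squared-Euclidean RDM equals combining the
  single-dimension RDMs with weights `w_d²`. This holds exactly and is
  asserted to machine precision in the tests.

Dissimilarities are never rank-transformed; the regression fits raw
values.

## Visuo-semantic model construction

`label_models` reproduces the two-experiment construction: a label
survives generation if ≥ `min_observers` (default 3 of 15) produced it
for at least one image; a validation cell becomes 1 at ≥ 75% agreement
(default panel 14). Manual curation of inconsistent/redundant labels is
modeled as an explicit exclusion list, not an algorithm. Merging
averages the most-correlated column pair (Pearson, which equals the phi
coefficient on binary columns) and *recomputes* all correlations after
every single merge, until the within-group maximum is ≤ 0.9. Two open
choices were resolved as follows and are deliberate package semantics:

* merging is restricted to dimensions within the same group (color,
  texture, …), so submodel sizes stay well defined;
* ties at the maximal correlation merge the lexicographically first
  name pair, making the procedure deterministic.

Each merge removes one column, so termination is guaranteed.

## First-level fitting

Per participant, region, and time point, the data pair vector `y` is
regressed on the predictor matrix `X` (one column per single-dimension
or single-layer RDM):

    minimize ‖y − X̃w − b‖² + λ‖w‖²   subject to w ≥ 0,

with `X̃` z-scored on training pairs and the intercept `b` unpenalized.
Because the standardized columns have zero mean on the training pairs,
the intercept decouples exactly (`b = mean(y)`), and the problem reduces
to nonnegative least squares on the augmented design
`[X̃; √λ·I]` — solved exactly by the Lawson–Hanson active-set method
(scipy's `nnls`). No iterative tolerance tuning is needed; the solver is
exact up to floating point.

Cross-validation is at the image level: a fold's test set is 8 images —
2 faces, 2 body parts, 4 inanimate, sampled uniformly within strata
("faces" pools human and animal faces, "body parts" pools human body
parts and animal bodies; this reading makes all three strata well
defined). Only test×test pairs are predicted (28 per fold), train×test
pairs are used nowhere, and folds repeat until every pair is covered;
per pair, predictions are averaged over covering folds. λ is chosen per
fold by nested cross-validation: training images are partitioned into
inner folds (round-robin within strata), error is scored on pairs among
held-out inner images, and ties go to the larger λ. The library default
grid is 20 log-spaced values in [1e−4, 1e2] with 5 inner folds;
predictors with zero training-pair variance are dropped from that fold
with a logged warning.

Fold geometry, standardization, and the per-λ augmented designs depend
only on stimuli and predictors, so they are precomputed once
(`CrossValPlan`) and reused across participants, regions, and time
points; per data vector only the NNLS solves remain. This is what makes
the time-resolved fit tractable on one CPU.

Note that with only one face (or body part) per test set a face–face
pair could never be jointly held out; coverage is provably unreachable
for such compositions and `fold_schedule` reports the uncovered pairs
instead of looping forever.

## Second-level partitioning

Cross-validated predictions enter a second-level GLM fit with
nonnegative least squares plus a free constant (absorbing homogeneous
dissimilarity shifts). Model performance is the regression
`R² = 1 − SS_res/SS_tot` (SS_tot about the mean of `y` at that time
point), not a squared prediction–data correlation; the two differ when
the prediction is miscalibrated, and regression R² is what a "variance
explained by the GLM" reading implies. Values are reported unclipped —
R² of a forced bad fit can be negative; baseline subtraction at the
inference stage handles bias. Second-level predictors are *not*
re-standardized: they are already calibrated predictions on the data
scale.

Unique variance of class A = R²(full) − R²(all classes except A).
Feasible sets nest under the nonnegativity constraint, so unique
variance is nonnegative up to solver tolerance (asserted ≥ −1e−6
throughout). For submodel analyses the reduced GLM retains all other
predictors and drops only the submodel of interest.

## Group inference

Each (measure, region) family: subtract the per-participant mean over
the closed-open baseline window [−200, 0) ms; Wilcoxon signed-rank test
across participants at each time point (one-sided against zero for
evaluation, two-sided for model comparison); Benjamini–Hochberg FDR at
q = 0.05 across the family's time points (BY available by option);
continuity criterion removing runs shorter than 10 samples (20 ms at
2 ms sampling); onset = first time of the first surviving run,
reported from the post-continuity mask.

The signed-rank p-value is exact for up to 25 non-zero values: zeros
are discarded, absolute values get average ranks, and the null
distribution of the rank sum is enumerated by subset-sum dynamic
programming over doubled ranks — equivalent to enumerating all `2^n`
sign assignments and therefore valid under ties, where classical exact
tables are not. Larger samples use the normal approximation with
continuity correction. The 80 Hz order-6 Butterworth low-pass
(`sosfiltfilt`, zero phase) exists for display only and never feeds
inference.

## Synthetic data

The generator replaces unavailable source-reconstructed recordings with
movies whose generative state is fully known:

* **Activations** — per layer, unit responses mix an image-specific and
  a category-prototype component; the categorical share grows with
  depth, then a softplus keeps rows non-constant. This reproduces the
  one qualitative property downstream analyses depend on (deeper layers
  emphasize category structure); it does not emulate receptive fields,
  retinotopy, or trained-network feature statistics.
* **Label experiments** — planted binary truths (category indicators,
  an animacy label, category-correlated feature labels, plus exact
  duplicates to exercise merging); observers endorse true cells with
  probability `1 − noise` and false cells with `noise/2`. At zero noise
  the validation stage recovers the planted matrix exactly.
* **Movies** — data pair vector `Σ_m w_m(t)·x_m + b + ε` with
  `ε ~ N(0, noise_sd²)` iid per pair, participant, and time point.
  Pair-level noise matches the regression's error model; a secondary
  pattern-level mode (noise on latent unit responses, then 1 − Pearson)
  exercises the correlation-distance nonlinearity that real data would
  introduce. Weight curves are piecewise-linear bumps that are exactly
  zero before stimulus onset.
* **Reversal scenario** — network-class weights rise from 50 ms in
  ROI-1; visuo-semantic weights rise from 140 ms in ROI-2; per-ROI
  amplitudes are rescaled so the mixed signal's pair-wise SD at the
  planted peak equals `signal_sd` (default 0.5) against `noise_sd`
  (default 0.2) — a moderate-noise regime in which ten participants
  suffice for reliable onset recovery while the prestimulus window
  stays null.

What passing tests on these data do **not** show: recovery under
realistic MEG noise spectra (temporally autocorrelated, spatially
structured), source-leakage between regions, or the empirical latencies
of real recordings. The planted onsets are arbitrary study conditions,
not predictions.

## Problem sizes

The library defaults mirror the full design (92 images in the
12/12/12/12/23/21 category composition, 2 ms sampling from −200 to
1000 ms, 20-value λ grid, 5 inner folds). The pipeline's `RunConfig`
defaults, used by the end-to-end validation and the acceptance script,
are a quarter-scale scenario chosen as the smallest design that retains
every structural element of the full analysis: 24 images in the same
category proportions, 10 participants, 150 time points (−100…198 ms),
two model classes (5 feedforward layers, ~12 semantic dimensions), a
5-value λ grid with 3 inner folds, and ~60–70 folds to pair coverage.
The no-signal false-positive control uses 200 simulated
(measure, region) families of 10-participant Gaussian null
trajectories over 250 time points.

## Known limitations

* The first level is embarrassingly parallel over participants and time
  points but currently runs serially.
* Exact signed-rank enumeration caps at n = 25 non-zero values; beyond
  that the normal approximation is used.
* `fold_schedule` samples folds randomly rather than constructing a
  minimal covering design, so the fold count varies with the seed.
* The pattern-level noise mode supports predictors with an explicit
  per-image score basis; arbitrary predictor RDMs have no unique
  pattern embedding.
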