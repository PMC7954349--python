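# Methods

## The modeling framework

The package treats a layered feedforward network as a family of candidate
visual systems of increasing representational abstraction: model *k* consists
of the network up to layer *k* plus a new linear decoder trained on the task
of interest. Comparing the family member by member against behavior and
neural data localizes the level of processing a task or a brain area
requires. Three analyses share this structure:

1. **Task decoding.** For each layer, activations of every unit are taken
   *before* the rectifying nonlinearity (normalization and pooling layers,
   which have no ReLU, are taken at their direct output). For videos,
   activations are extracted per frame and averaged over time within each
   16-frame bin (a temporal extractor would consume bins whole and average
   over its temporal output dimension). The activations are standardized per
   feature and projected to principal-component space, always retaining the
   full set of components — min(n_train − 1, n_features) for a centered
   matrix. Standardization and PCA parameters are estimated from the
   training stimuli only. A linear SVM is then trained on the task and
   scored on training and held-out stimuli. A pixel-space model (flattened
   pixels through the identical standardize+PCA pipeline; videos contribute
   their within-bin frame-mean image) serves as layer 0.

2. **Behavioral-signature prediction.** The vector of per-condition percent
   correct is logit-transformed and regressed onto layer features with
   partial least squares (3 components for two-object transformation tasks,
   10 otherwise; predictors centered but not rescaled, responses centered).
   For 2AFC experiments the predictor for a pair is the target's feature row
   minus the distractor's. Explained variance is the squared Pearson
   correlation between predicted and observed logits (×100), computed on an
   independent generalization phase when the experiment has one and by
   leave-one-out cross-validation otherwise.

3. **Representational similarity.** Response patterns (neural: per-unit
   repetition-averaged, latency-shifted, z-scored firing rates per 16-frame
   bin; model: per-bin feature vectors) are correlated pairwise to give
   1 − Pearson RDMs. Neural-model correspondence is the Spearman correlation
   of the strictly-upper RDM triangles, divided by the area's noise ceiling:
   the Spearman-Brown-corrected mean split-half RDM correlation over random
   splits of the repetitions (1000 by default). RDM ensembles are embedded
   with non-metric MDS on 1 − Spearman distances; the neural-vs-model
   distance ratio divides the mean neural-to-model RDM distance by the mean
   distance between RDMs of different models.

Uncertainty throughout is leave-one-out jackknife:
SE = sqrt(((n−1)/n)·Σ(θ₋ᵢ − mean)²), CI = estimate ± 1.96·SE. The resampling
axis is an explicit parameter of each analysis (transformation cells,
stimuli, target-distractor pairs, or neural units), never inferred.

## Numerical and convention choices

* **Decoder objective.** mean hinge loss + (λ/2)‖w‖², bias unregularized,
  minimized with L-BFGS from a zero start (tolerance 1e−8, ≤1000
  iterations, no random restarts). λ defaults to 1/n_train, the default
  regularization of the linear-classifier implementation this mirrors. At
  fixed λ the objective is exactly invariant under duplication of the
  training set. Note that with this default the decoder may trade single
  margin violations against regularization even on linearly separable data
  (observed on the lowest-dimensional fc layers).
* **Ties.** A decision value exactly 0 (yes-no) or an exact target-distractor
  tie (2AFC) is credited 0.5 — unbiased and measure-zero in practice.
* **Zero-variance features.** A feature whose training spread is zero — or
  at floating-point rounding level, sd ≤ 1e−12·(|mean|+1) — standardizes to
  0 everywhere. Without the rounding floor, near-constant pre-ReLU units
  amplify summation noise into O(1) garbage columns whose nonzero mean then
  dominates the PCA. For the same reason the standardized training matrix is
  re-centered before the SVD and the correction folded into the stored mean.
* **PCA determinism.** Component signs are fixed by making each axis's
  largest-magnitude loading positive.
* **Logit clipping.** ε = 0.5/n_trials (half-a-count); n_trials = 0 is a
  sentinel for exact proportions (no clipping, saturation is an error).
* **Noise-ceiling splits.** Odd repetition counts split ⌈k/2⌉/⌊k/2⌋ at
  random; per-unit standardization is redone within each half so the halves
  stay independent.
* **Latency handling.** A unit's response latency (an input, never
  estimated here) is converted to a whole-bin offset at the 533 ms bin
  duration (16 frames at 30 fps) and shifts the unit's read-out window along
  a correspondingly padded time axis.
* **Non-metric MDS.** Kruskal stress via seeded restarts (50 by default),
  best solution kept; convergence threshold 1e−12 so duplicate inputs
  collapse onto coincident points.
* **Video 2AFC aggregation.** Bin i of the target is compared with bin i of
  the distractor and the nine bin outcomes averaged into the video-pair
  score (an all-pairs alternative is available). Training-set evaluation
  enumerates every target×distractor combination; test evaluation uses the
  fixed pairing in the manifest.
* **RF-matched rescaling.** The four published content sizes (53, 99, 129,
  137 px on a 227 px canvas) are shipped verbatim as named presets. They are
  not mutually consistent with a single pixels-per-degree factor, so they
  are never recomputed from the 2.2 px/° helper constant.

## The built-in extractor

Pretrained networks are optional external inputs; the analyses themselves
are architecture-agnostic behind a small extractor contract (given a batch
and a layer name, return one pre-ReLU activation row per input). The layer
registries describe the published eight-block architectures for naming and
plotting. The bundled "tinynet" — four conv/max-pool stages (8/16/16/32
channels, 64 px RGB input) plus two fully connected layers, Glorot-uniform
weights with zero biases, pure numpy — makes every analysis runnable and
reproducible from a seed. Random weights are not a stand-in for trained
ones scientifically: they give weaker and flatter layer effects, which is
exactly the regime the randomly-initialized control analyses probe.

## What the synthetic data emulate — and what they do not

The generators are pure functions of their seed and parameters and write to
the same on-disk formats the loaders read.

* **Transformation grid**: two smooth closed silhouettes (random Fourier
  descriptors, harmonics 2-8, anti-aliased with an edge width proportional
  to object size so sizes are related by pure rescaling) over 6 sizes
  (15-40°) × 9 in-plane rotations (±40°), training role on the 14-cell cross
  (middle-size row plus 0° column), test on the 40 remaining cells per
  object. In-plane rotation stands in for the azimuth rotation of the
  original 3-D objects.
* **Silhouette set**: one reference plus 11 distractor silhouettes at five
  sizes (15-35°), all training-phase (the matching analysis is LOOCV).
* **Category videos**: 150 frames, 64 px; targets are an articulated
  two-part figure (body plus heading-locked head) on a smooth trajectory;
  natural distractors have the identical parts moving independently —
  category is carried by spatial configuration, not by part inventory,
  sizes, or speeds. Scrambled distractors apply per-frame 2-D Fourier phase
  randomization that preserves each frame's amplitude spectrum, with one
  phase field shared across frames (so scrambled clips keep temporal
  correlation) and the DC phase pinned so mean luminance survives. In
  `low_level_equalized` mode (default) every frame is affinely mapped to a
  fixed mean luminance (0.55) and RMS contrast (0.05).
* **Behavioral signatures**: p = logistic(intercept + w·features) with
  sparse ground-truth weights rescaled so the logit drive has SD 1.2 across
  conditions and intercept 0.7 (above-chance average, realistic 40-90%
  range); reported performance is Binomial(n_trials, p)/n_trials with
  n_trials = 80 by default.
* **Neural populations**: each unit is softplus(random projection of a known
  layer's features, unit-normalized to SD 1.5) plus i.i.d. Gaussian trial
  noise (SD 0.5 by default), 40 units and 10 repetitions per area, latencies
  drawn uniformly from 40-120 ms.

None of this approaches photorealism, real rat behavior, or real spiking
statistics (no Poisson variability, no correlated noise, no adaptation).
Passing tests therefore show that the *analysis machinery* is correct and
that ground truth planted in the generators' terms is recovered — not that
any scientific claim about real rats is reproduced. Real stimuli, behavior
tables, pretrained weights, and recordings plug into the same loaders and
templates when available.

## Problem sizes and design choices in the reported runs

The shipped experiment templates run at deliberately moderate scale — 108
grid stimuli, 60 silhouettes, 15-30 videos of 150 frames at 64 px, 40-unit
populations — sizes at which the full synthetic suite (all templates plus
RSA) completes in a few minutes on one CPU core while leaving every
analysis path exercised.

Two empirical caveats worth knowing:

* **Interpolation regime in signature recovery.** With full-rank PCA
  features the predictor count nearly equals the condition count, and
  held-out PLS predictions then carry substantial model-estimation variance
  (~15% of signal lost) even when the in-sample fit captures >95%. Recovery
  to within a few points of the signature's split-half reliability is
  obtained when conditions comfortably outnumber feature components (e.g.,
  60 conditions over a 16-unit layer).
* **Generating-layer recovery margins.** Early layers' RDMs are mutually
  similar on the video set (inter-layer Spearman ≈ 0.9), so an area
  generated from conv1 is recovered at conv1 or an adjacent layer in ~85% of
  seeds at the default 40 units/noise SD 0.5, whereas conv4 is recovered
  essentially always. Sharper early-layer identification needs more units
  or lower trial noise.
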