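# Methods

## Model

The classifier scores pain from a single pre-cropped rat face image. A
convolutional backbone `f` maps the `d×d×3` input to an `M×M×d_x` feature
map, read row-major as `K = M²` regional feature vectors (region `j` sits at
grid cell `(j div M, j mod M)`; the convention is fixed so tests and
heat-maps agree). A shared affine scorer `g: R^{d_x} → R` is applied to
every region; sigmoids of its outputs, normalised by their sum, give the
attention (pain-contribution) scores `β`. The prediction is
`softmax(h(Σ_j β_j x_j))` with `h` affine. Two backbones are registered:

* `resnet18-conv` — the ResNet-18 convolutional stack (stem, four stages of
  two basic blocks with batch normalisation). At 224×224 input it yields
  `M = 7`, `d_x = 512`. Initialisation is random by default; whether to use
  pretrained weights is left open deliberately, and the architecture makes
  no assumption either way.
* `tiny` — stride-2 3×3 conv/ReLU blocks halving the side until it reaches
  `M = 4`. Used for all desk-scale experiments.

All tensor computation runs on a small in-package reverse-mode autograd
engine over float64 numpy arrays (broadcast arithmetic, matmul, im2col
convolution, max-pooling, indexing with scatter-add backward, stable
log-softmax). Every primitive's gradient is checked against central finite
differences in the test suite. Single-threaded numpy makes every run a pure
function of its integer seed; checkpoints store all parameter and buffer
arrays plus the config and reject loading into a mismatched config.

## Objectives

Cross-entropy uses log-softmax directly during training; the numeric API
clamps probabilities at 1e-12 before the log so the loss is always finite.
The pain-related score calibration (PRSC) term for one sample is

    (1/K_h) Σ_{j≤K_h} max{0, δ − (β^h_j − β̄^r)}

with `β^h` the `K_h` largest scores (ties broken toward lower region index
via a stable sort, for determinism) and `β̄^r` the mean of the remaining
`K_r = K − K_h`. Because the smallest top score is still ≥ every non-top
score, each gap is nonnegative and the loss lies in `[0, δ]`. Gradients flow
through both `β^h` and `β̄^r`; no stop-gradient is applied, since the
formulation gives no reason for one. The joint objective averages
`CE + λ·PRSC` per sample over the batch. Note a structural consequence of
the defaults: with `Σβ = 1`, the hinge vanishes only when the `K_h` top
scores are exactly `β̄^r + δ` each, which for `δ = 0.2, K_h = 5` forces the
non-top scores toward zero — the regularizer is a hard concentration prior,
and `δ` is deliberately exposed in config.

PRSC is applied per sample and then averaged (the per-sample reading of the
batch objective); a per-batch alternative on mean scores was considered and
rejected as a different estimand.

## Training

Augmentation is resize to 256 (bilinear), random 224 crop, horizontal flip
with probability 0.5 — the probabilistic flip gives the same flip-augmented
exposure as literally doubling the dataset; a `static_flip_double` flag
reproduces the literal doubling. Optimiser defaults: Adam, lr 1e-4, weight
decay 0.01 applied as classical (coupled) L2 on the gradient, batch 64,
30 epochs — the epoch count is a convergence choice, not prescribed.
The last incomplete minibatch is kept (datasets are small). Test-time
preprocessing is a deterministic direct bilinear resize to the input size by
default, with an optional resize-then-center-crop mode that reproduces the
training-time geometry. Non-finite losses abort with the epoch, batch and
regularizer settings in the message.

## Label aggregation

AU-level votes are 0/1/2 or "uncertain". Stage 1 (five raters): ≥4
identical numeric votes give a high-confidence consensus; anything else —
including ≥4 "uncertain" votes, which never form a numeric consensus —
goes to stage 2. Stage 2 adds three raters; the AU is accepted iff some
numeric score appears ≥5 times among all eight votes. An image gets a label
(the rounded mean of accepted AU scores) only when ≥3 of its four AUs were
accepted; otherwise it is low-confidence and unlabelled. Rounding is
half-up by default — 0.5 rounds toward more pain, the conservative
direction for welfare monitoring — with banker's rounding behind a flag.

## Evaluation protocol

Labels are binarized (0 → NoPain, 1/2 → Pain; Pain is the positive class)
and folds are leave-one-rat-out: fold `s` tests every image of subject `s`.
Each fold trains a fresh model from the same seed, so fold differences
reflect data, not initialisation. Headline metrics are micro-pooled:
confusion counts are summed over folds and F1/accuracy recomputed from the
sums; unweighted macro averages are reported alongside. The sweep harness
varies one of (λ, δ, K_h) at a time over the published grids
(λ ∈ {0.05, 0.1, 0.5, 1, 1.5}, δ ∈ {0.05, 0.1, 0.15, 0.2, 0.5},
K_h ∈ {3, 5, 10, 15, 20}) while holding the other two at defaults, skipping
K_h ≥ K with a warning.

The per-fold training-count table is pure arithmetic on per-subject totals
(column sums minus the held-out subject's row); the published per-rat counts
ship in `painseeker.ratspain` and the pipeline reproduces the published
fold table exactly from them.

## Synthetic benchmark

The generator emulates the structure of the real data, not its appearance:

* **Subject identity** — each subject has a unique smooth random texture
  (Gaussian-filtered noise, σ = side/10, amplitude 0.10) over a common mean
  gray of 0.42. Identity is deliberately not a brightness level: with few
  subjects, a per-subject brightness code correlates with each subject's
  class balance and becomes a shortcut that anti-generalises across
  leave-one-subject-out folds, which would measure the confound rather than
  the signal.
* **AU regions** — four disjoint axis-aligned squares (side 0.20 of the
  image) at fixed canonical positions for ears, orbital, nose/cheek and
  whiskers. Squares at known positions make grid-cell overlap, and hence
  the attention-localization score, exact.
* **Pain signal** — inside visible patches, pain shifts the mean intensity
  and adds a per-AU oriented grating, scaled by `pain_effect` (default
  0.15 = 3× the pixel noise σ of 0.05); severe pain scales the effect 1.5×.
  A small fraction of pain images (1%, matching the published rarity of
  severe scores) is severe.
* **Pose nuisance** — "moderate" poses translate all patches by a common
  offset up to 0.10 of the side, "extreme" poses by up to 0.18 and
  additionally occlude each patch (replace it with background) with
  probability `occlusion_fraction` (default 0.5). Translation-plus-dropout
  reproduces the mechanism that hurts real scoring — pain-relevant regions
  moving and disappearing — without 3-D rendering.
* **Counts** — per-subject (NoPain, Pain) counts default to the published
  per-rat imbalance at 1/8 scale (143 images), keeping the imbalance
  pattern while fitting desk-scale budgets.

What passing on this benchmark does *not* show: robustness to real fur
texture, lighting, within-subject appearance drift, or rater noise — the
generator's labels are exact and its signal is stationary by construction.

The localization score of an attention vector is the fraction of β mass on
grid cells overlapping any visible AU patch; under uniform or simplex-random
attention its expectation is the AU cell fraction, which the tests verify by
Monte Carlo.

A note on the no-signal null: with `pain_effect = 0` the labels are
independent of the pixels given the subject, so any classifier's fold-s
accuracy is a mixture `q_s·p_s + (1−q_s)(1−p_s)` of that fold's class rates
(`p_s` the pain rate, `q_s` the fraction predicted Pain). The pooled value
is therefore confined to `[Σ w_s·min(p_s, 1−p_s), Σ w_s·max(p_s, 1−p_s)]`
(≈ 35–65% under the default counts) and cannot exceed the majority rate
beyond sampling noise — but it is *not* centred on the majority rate: a
model memorises per-subject label priors from the training subjects, and
those priors anti-generalise to the held-out subject, typically landing the
pooled accuracy a few points below the global majority. The null test
asserts exactly these two facts (one-sided majority bound, hard
label-independence interval) rather than a symmetric band around the
majority rate, which would be the wrong null for a leave-one-subject-out
protocol with imbalanced subjects.

## Desk-scale study conditions

The benchmark harness (`painseeker.benchmark`) fixes: 64×64 images, six
subjects at 1/8 published counts, pose mix 0.4/0.4/0.2, pain effect 3× noise,
tiny backbone (width 8, `d_x` 16, K = 16), and training with Adam lr 1e-3,
batch 16, 40 epochs, weight decay 0.01, evaluated with the
resize-center-crop mode so train and test share the same resampling
geometry (on native-resolution synthetic images a raw-pixel evaluation path
would be the only unresampled image the network ever sees). The epoch count
was set where training accuracy saturates on held-in data; with fewer
epochs some folds remain stuck at a constant-class prediction and the
evaluation measures optimisation failure instead of generalisation. The
regularizer comparison trains both arms (λ = 0.1 vs λ = 0) from identical
seeds on identical data.

## Numerical choices and edge cases

* F1 with no positives anywhere (TP = FP = FN = 0) is defined as 0 with a
  warning; accuracy of an empty evaluation is an error.
* Attention normalisation requires K ≥ 2; K_h ≥ K is a configuration error.
* LBP follows the convention: 8 points counter-clockwise from angle 0,
  bilinear off-grid sampling, bit set iff sample ≥ centre (constant
  neighbourhoods code to 255); raw 256-bin histograms per grid cell,
  L1-normalised, cells partitioned near-equally, border pixels without a
  full circular neighbourhood excluded. The variant names R1/R3 refer to
  the sampling radius with 8 points. Uniform-pattern LBP is intentionally
  not the default (nothing indicates it); the SVM is linear with C = 1.
* The degenerate single-class training fold in the SVM baseline falls back
  to a constant predictor with a warning rather than failing the batch.

## Known limitations

* The ResNet-18 backbone is randomly initialised; ImageNet-pretrained
  weights are not bundled, so full-scale results on real data depend on the
  caller supplying training at scale.
* The synthetic generator's pose model is 2-D translation plus dropout;
  out-of-plane rotation is not simulated.
* Training is single-threaded numpy float64: bit-reproducible, but not fast
  beyond desk scale.
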