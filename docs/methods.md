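# Methods

## Problem and model

`dermprio` implements a triage pipeline for dermatology referral cases.
Each case carries an image of a single skin lesion, optional patient
metadata (age, sex), a 13-way differential diagnosis assigned at the
specialist consultation, and a 3-level booking priority: normal (N),
priority (P), high priority (HP).

The central object is the **knowledge map** K, a 13x3 table elicited
from a panel of dermatologists: row c gives the expected percentage
distribution of priorities for diagnosis c (mean and standard deviation
across the panel; rows sum to exactly 100). Priority prediction from a
diagnosis score vector s (length 13, nonnegative) follows one of:

- **Naive fusion.** Per-priority aggregation of the score-weighted map:
  sum mode computes `s @ K_mean` (a vector-matrix product), max mode
  takes `max_c s_c * K_mean[c, p]` for each priority p. For a one-hot
  (ground-truth) diagnosis, both reduce to reading off row c; the argmax
  of that row is the **modal priority**, and triaging every case this
  way ("Naive GT") is the performance ceiling of any
  diagnose-then-map pipeline.
- **Simple fusion.** `alpha * priority_scores + beta * naive_scores`,
  combining a dedicated 3-way priority classifier with the
  knowledge-map route. The naive term is normalised to unit sum first
  so that alpha and beta weigh comparable vectors (for sum-mode fusion
  of a unit-sum diagnosis vector the total is exactly 100, so this is a
  fixed division by 100). Defaults alpha=2, beta=1, the best reported
  setting for this task.
- **Combined training.** A shared backbone with a 13-way and a 3-way
  head; the fused score above is formed *inside* the training loss,
  `L = lambda_dx * CE(diagnosis) + lambda_pr * CE(softmax(fused))`, so
  the diagnosis head receives gradient through the knowledge map.
  Defaults lambda_dx = lambda_pr = 0.5; the analytic gradient of the
  fused term is verified against finite differences in the test suite.

Argmax decisions break ties toward the higher-severity level — the
clinically conservative choice; the source material does not specify a
rule. An all-zero score vector returns N with a warning rather than
raising, so pipelines never crash on a dead head. The std columns of
the knowledge map are validated on load but unused by fusion (reserved
for a future perturbation mode).

## Evaluation conventions

Metrics are per-class sensitivity (recall), precision and F1, plus
accuracy, macro F1 (unweighted mean) and weighted F1 (support-weighted
mean), all in percent. Zero denominators yield 0. Aggregates use
*unrounded* per-class values: rounding per-class F1 before weighting
shifts the weighted F1 by 0.01 on the balanced test partition (51.01
vs 51.02), which the regression tests pin down. Reported numbers use
2-decimal half-up rounding. Per-class tables are displayed HP, P, N
(most severe first); internal order is N < P < HP by severity.

`naive_gt_from_counts` never samples: the confusion matrix follows
arithmetically from a diagnosis-by-priority count table, because every
case of a diagnosis receives the same modal priority.

## Lesion cropping

Saliency-to-mask extraction: (1) compute the map's mean intensity mu;
(2) overwrite four corner squares (side 10% of min(H, W)) with mu,
silencing the border noise activation maps typically show; (3)
binarize strictly above `c * mu` (default c = 1.0 — the original
thresholding is described only as empiric, so the factor is exposed in
`CropConfig`); (4) keep the 8-connected component whose centroid is
nearest the image centre. No survivor yields an empty mask.

Mask reconciliation: with an activation-derived mask `gc` and an
external segmenter mask `dl` (resampled nearest-neighbour to `gc`'s
shape), accept `gc` if the overlap strictly exceeds 50% of `gc`'s
area, else `dl` if it strictly exceeds 60% of `dl`'s area, else the
empty mask — meaning the original image is used. The output is always
one of the inputs or empty, never a blend.

Square crop: take the tight bounding box, extend the smaller dimension
by half the side difference on each end (odd differences put the extra
pixel on the far side), dilate all four sides by
`tolerance_pct/100 * r` with r = half the larger bounding-box dimension
(the "approximate radius"; studied tolerances 0/10/30/50%), then shift
the window back inside the image, clipping an axis only when the window
exceeds the image itself (shift-then-clip keeps the window square
whenever it fits). Coordinates are 0-based half-open. Cropped patches
are resized with nearest-neighbour interpolation (introduces no new
intensities), 300 px default output.

## Training schedules

All schedule generators are pure functions of their specs and emit
per-epoch `ScheduleState` records (active classes, trainable blocks,
learning rates, loss weights, batch contract):

- **Frozen-block fine-tuning.** Phase k trains the last
  `initial_unfrozen + k` block groups plus the head, 3 epochs per
  phase; head learning rate 1e-4, unfrozen body 1e-5 (the full-scale
  defaults). The priority branch starts from the last three blocks and
  runs six cycles.
- **Branch (B-CNN) hierarchies.** Two-level (benign/malignant, with
  neoplasms of unclear behaviour grouped as malignant) or three-level
  (melanocytic/pigmentation; shipped as an editable YAML because the
  exact placement of a few classes is clinically ambiguous, with
  per-sample overrides for BCC and ActKer pigmentation). The total loss
  is the dot product of per-level cross-entropies with an
  epoch-scheduled weight vector; packaged handover schedules:
  two-level [0.98,0.02] -> (6) [0.3,0.7] -> (12) [0.1,0.9] -> (18) [0,1];
  three-level [0.97,0.02,0.01] -> (6) [0.1,0.8,0.1] ->
  (12) [0.1,0.2,0.7] -> (18) [0,0,1]. Branch heads are fully connected
  stacks with batch-norm and dropout.
- **Curriculum.** Classes ordered easiest-to-hardest by flat-model
  per-class F1 (packaged reference values), with the rarest class
  forced last regardless of score; training starts with the four
  easiest classes and, after each full unfreeze cycle (six phases of
  three epochs), refreezes everything and introduces the next class.
  Batches always hold one sample per active class, so the batch size
  grows 4 -> 13.
- **Stratified batching.** Each class contributes exactly
  `samples_per_class` (default 200) indices per epoch — a random
  subset when abundant, sampling with replacement when rare — arranged
  into class-transversal batches (13x1 for diagnosis, 3x4 for the
  priority branch). Deterministic given the seed.
- **Metadata late fusion.** Age/100 and a 0/1 sex indicator appended to
  the backbone feature vector before the classifier. The encoding is a
  package choice; only the inputs (age in years, sex category) are
  given by the data model.

## Numpy backend

No deep-learning framework is part of the package's dependency set; a
compact numpy backend (`dermprio.nn`) provides conv / dense /
batch-norm / dropout layers with manual backprop, Adam, and a
multi-head block model with by-name freezing and intermediate taps for
branch heads. Backprop stops below the earliest trainable block. It is
sized for tiny backbones (3-4 conv blocks, 32x32 images) on one CPU;
the block/head abstraction is what full-scale backbones (e.g. an
EfficientNet's seven blocks) map onto.

Because tiny backbones start from random weights rather than
large-scale pretraining, the desk-scale experiments use larger
learning rates (head 1e-2, body 3e-3) than the full-scale defaults
carried in the schedule states; the trainer takes either.

## Synthetic cohort

The generator emulates the structure of the private referral dataset:
13 diagnosis classes with pairwise-distinct lesion appearance (one hue
per class plus systematic texture amplitude, border irregularity and
size differences), exact elliptical-harmonic ground-truth masks, hair
artifacts drawn strictly outside the lesion so masks stay exact, age
from a truncated normal (mean 55.84, sd 22.18, clipped to [0, 100]),
sex male with probability 1406/3427, and priority sampled from the
knowledge-map row of the case's diagnosis (multinomial on mean/100;
std unused). Label-only generation (`render_images=False`) supports
large statistical checks cheaply. Defaults: 64 px images; the training
experiments use 32 px via explicit config.

What passing tests show — and do not. Synthetic classes are separable
by design, so a tiny CNN recovering >90% diagnosis accuracy and
reaching the analytic Naive-GT priority ceiling demonstrates that the
schedules, fusion algebra and evaluation plumbing are correct, not
that any model attains such numbers on real referral photographs,
where reported diagnosis accuracies are under 50%.

Desk-scale problem sizes: the recovery experiment trains on 36 cases
per class (12 per class held out) at 32x32 for 15 epochs; the
chi-square check of priority-given-diagnosis uses 2000 label-only
draws per class at significance 0.01.

## Numerical choices and degenerate inputs

- Knowledge-map row sums validated to 1e-9; fusion math stays on the
  percent scale as printed, normalisation applied only where stated.
- Tolerance margins round half-up to whole pixels; tolerance dilation
  is monotone pre-clipping.
- Strict inequalities in the mask-reconciliation thresholds.
- Empty masks are values, not errors, through the whole crop path.
- Chi-square goodness-of-fit drops zero-probability cells (their
  observed counts are asserted zero).
- All samplers, initialisers and generators take explicit seeds;
  reruns are byte-identical.

## Known limitations

- The three-level hierarchy mapping is a best-effort clinical reading
  shipped as config, not a verified ground truth.
- Early stopping is not implemented; schedules run to completion
  (validation-loss stopping is noted as unresolved in the source
  protocol, and the desk-scale runs are short).
- The backend has no GPU path and no general graph autodiff; custom
  losses require manual gradients (the combined loss's gradient is
  finite-difference tested).
- Augmentation is a light implementation of the stated ranges; it is
  off by default in the desk-scale experiments.
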