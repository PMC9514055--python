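# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `gazecam` pipeline, in the order the method runs.

## Gaze model and display geometry

Stimuli are presented on a simulated 1920×1080 screen.  An image of side
`image_size` px is displayed scaled by `scale_factor` (default 2) and, by
default, centered; analysis runs at the original image resolution, with
gaze coordinates mapped back by `floor((screen − origin) / scale)` over a
half-open display rectangle.  Gaze is simulated at 1,000 Hz for a 1,500 ms
presentation as a two-state renewal process:

- an initial **central fixation** at the screen center (the fixation-cross
  location), held for a saccade latency drawn per trial from
  N(`central_onset_ms`, `central_onset_jitter_ms`) = N(175 ms, 25 ms),
  clipped to [80, 400] ms — the ~150–200 ms feedforward/preattentive
  interval;
- a first **object saccade** that lands on the face-ROI centroid with
  probability `face_bias` (when a face is present) or on the object
  centroid otherwise, with isotropic landing noise
  (`saccade_noise_px` = 8 screen px); ROI centroids are snapped to the
  nearest mask pixel when a clipped (concave) ROI puts the raw centroid
  outside the mask;
- subsequent **refixations** at `refixation_rate` = 2 s⁻¹ (exponential
  intervals), again face-biased or else targeting a uniformly drawn object
  pixel; within-fixation tremor has SD `fixation_jitter_px` = 3 px.

Participant heterogeneity: each simulated participant perturbs the cohort
means (onset N(·, 20 ms); face bias N(·, 0.05) clipped to [0, 1]; noise,
tremor and refixation rate by log-normal factors with σ = 0.2).  All
randomness flows from one master seed through named sub-streams (images /
participants / trials), so any stage can be reproduced in isolation.  The
generator does not model pupil size, blinks, smooth pursuit or
microsaccades, and fixation counts/durations are stated assumptions rather
than fits — no per-participant fixation statistics exist to calibrate
against.

## Synthetic stimuli

Each image is a drawn object on a mid-gray background (weak smooth
chromatic noise, σ≈0.05; fine pixel noise σ = 0.008).  Category identity
is carried by partially redundant cues:

- **hue pairs**: the 12 default categories form 6 hue pairs (warm hues for
  the 6 animate categories, cool for the 6 inanimate ones); pair members
  share body color and shape family (animate bodies are ellipses,
  inanimate ones angular shapes);
- **fixated detail**: every image contains a fine grating patch
  (0.2 cycles/px) whose *contrast* disambiguates the pair (≈0.08 vs
  ≈0.50).  On animate images with a face (probability
  `face_probability` = 0.74, chosen so roughly 133 of 360 images carry a
  face) the patch is the face, placed at the top of the body; otherwise it
  sits at the body centroid — in both cases exactly where the simulated
  gaze concentrates.

This makes the fixated detail *partially* class-discriminative by
construction: the spotlight blur (σ ≈ 2 px at 64 px resolution) removes
essentially all energy at 0.2 cycles/px, so Anti-Spotlight training erases
the within-pair cue while the hue cue survives.  Bodies are composited
with anti-aliased (soft) edges so silhouette boundaries contribute little
high-spatial-frequency energy, keeping fine-texture channels selective for
the detail patches.  Objects are displaced laterally (±8–18% of the image)
and slightly downward so the central fixation onset does not coincide with
the object or its face — the separation that produces the early-central /
late-on-face time course.

What the generator deliberately does *not* emulate: natural-image
statistics, context that predicts category (so "contextual shortcut
learning" is unavailable here), within-category pose/size/viewpoint
variation beyond mild jitter, and multiple objects per image.  Passing
tests therefore show that the *pipeline* measures the planted effects
correctly, not that the effects would take these magnitudes on natural
images.

## Heatmaps

Samples inside the image are grouped on the presentation clock into
non-overlapping 50 ms windows over the first 1,000 ms (20 windows;
out-of-image samples are dropped but do not shift boundaries), or pooled
over the whole presentation for the manipulation-driving map.  Windows of
shifting onset are read as contiguous, consistent with a maximum of 20
discrete windows; a cumulative mode is available as a flag.  Accumulation
is per-pixel sample counting (dwell time at 1 kHz) — no fixation-event
parsing.  Smoothing is Gaussian, SD 20 px at the 227 px reference
resolution and scaled proportionally otherwise (≈5.6 px at 64 px),
truncated at 4 SD with reflective borders (mass-conserving).  Maps are
peak-normalized (max = 1) per participant, averaged across participants,
and re-normalized; peak normalization is the dialect that makes a value
threshold at "the first tertile" meaningful.  All-zero maps stay all-zero
and are tagged `normalization="none"`.

## Spotlight manipulation

The keep mask is `density ≥ 1/3` (HS) or its complement (AS) on the
peak-normalized value range — a *value* threshold, not a pixel percentile:
a percentile rule would blur ≈33% of pixels by construction, whereas a
value threshold on a focal map blurs most of the image in HS (≈86% here;
the reference conditions report ≈76%) and little in AS.  Blur and taper
are windowed Gaussians (W = 30/SD = 7 and W = 35/SD = 9 at 227 px, scaled
proportionally); even window sizes are promoted to the next odd size to
keep the filters zero-phase.  The taper softens the *mask* (alpha
compositing of sharp over blurred), not the composited seam.  Ratio-mixed
datasets select `round(ratio/100 × n)` images per category by a seeded
draw; manipulated images are derived once per dataset and reused across
runs.

## Backbone and fine-tuning

The desk-scale backbone (`"small"`) is three conv layers
(24/48/96 channels, stride-2), global average pooling, one frozen dense
layer (256 units) and the trainable classification head; an
`"alexnet-like"` preset (5 conv + 3 dense) exists as a configuration
option.  Design rationale: with a frozen random feature extractor, a
position-specific dense layer cannot read cues tied to a movable patch,
whereas pooled channel energies are position-invariant — GAP is what makes
localized texture cues learnable by a linear head, and it gives the
classical GAP-CAM gradient structure.  Frozen weights are random
(He-normal) and calibrated layer-sequentially on seeded generic
smooth-blob probe images: conv layers are rescaled (scale only) to unit
pre-activation SD — biases stay zero so a mean-gray background yields zero
activations and Grad-CAM mass stays on objects — and dense layers are
standardized per unit with a pre-activation SD target of 4, which
conditions head training well enough that the fixed recipe converges
within its epoch budget.  Inputs are centered by subtracting 0.5.

Fine-tuning replaces the head and trains only it: SGDM (momentum 0.9,
unstated in the source recipe and configurable), mini-batch 42, base
learning rate 1e-4 with a ×20 factor on the replaced layer, at most 30
epochs, early stopping when validation loss fails to improve for 5
consecutive epochs, best-validation weights restored, no augmentation.
The validation split (fraction 0.2, an assumption) is stratified by
category so every class stays covered at n = 30/category.  Runs derive
per-run seeds from a master seed (head init + split shuffle); 10 runs per
condition by default, 5 per ratio in the scaled-down trade-off sweep (the
reference analysis uses 23 and 10).

## Grad-CAM

Channel weights are the spatial mean of the gradient of the *true-class*
score at the last conv layer (misclassified images included); the map is
the rectified weighted channel sum, bilinearly upsampled to the input
size, then min–max normalized.  The gradient target is the pre-softmax
logit (invariant to a constant shift of all logits; softmax probability is
available as an option — Pearson r downstream is invariant to affine
rescaling, so the normalization choice is inert for similarity).  A map
that is identically zero before normalization is kept all-zero and
flagged; degenerate maps are dropped from correlation records with a
logged reason, never silently zeroed.  Saliency is static per (run,
image): maps do not vary across time for static images.

## Metrics

Correlations are computed per image over flattened pixels and only then
aggregated — never pooled across images.  r is clamped to ±(1 − 1e−7)
before atanh.  The face-detection index is the raw mass ratio inside /
outside the face ROI with an ε floor (1e−9 × total mass; hitting the
floor is flagged as capped): the mass-ratio reading, rather than an
area-normalized density ratio, is what yields low scores when attention is
spread across the image.  Images without a face ROI are excluded from
face analyses.  Group summaries use seeded percentile bootstrap CIs
(B = 2,000) resampling records within each cell; cells with fewer than two
records are reported missing, not zero.  Inferential statistics
(Welch-ANOVA, Kruskal–Wallis, Wilcoxon, ANOVA-type statistics,
dependent-correlation tests) are deliberately not reimplemented: the
module emits tidy per-image record tables that any stats tool can consume.

## Problem sizes and expected behavior

The default end-to-end configuration — 12 categories × 30 images at
64×64 px, 23 simulated participants, 10 runs per condition, AS ratio sweep
100/50/0% × 5 runs — was chosen so a complete run finishes in minutes on a
single CPU; kernel windows and smoothing SDs scale proportionally from
their 227 px reference values.  Under these conditions the pipeline
reproduces the paradigm's directional signature: mean Fisher-Z similarity
of AS runs falls well below STD runs (gap ≈ 0.06–0.10 across master
seeds), the gap is larger for face-present images, the model
face-detection index drops under AS while the human index is far higher
than any model's, per-window similarity roughly doubles after the
simulated saccade latency, and across the AS ratio sweep both accuracy and
similarity rise monotonically toward the STD baseline as the manipulated
fraction shrinks.  The AS accuracy cost at this scale (≈20 pp) is larger
than in the reference conditions (≈7 pp): synthetic pairs have only two
cues, so deleting one is more damaging than in natural images.

## Known limitations

- The frozen backbone is randomly initialized, not pretrained on a large
  corpus; absolute similarity values and accuracy costs are not comparable
  to pretrained-network results, only the directional contrasts are.
- Grad-CAM resolution is the last conv grid (6×6 at 64 px input), so fine
  spatial claims below that scale are meaningless.
- The human face-detection index here (~0.6) is far below values obtained
  with tight real-face ROIs; the synthetic face ROI is small relative to
  landing noise and smoothing.
- `simulate_cohort` holds full sample streams in memory per participant;
  for very large cohorts write per-participant CSVs (`out_dir=...`)
  instead.
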