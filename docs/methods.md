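# Methods

## Scope and data model

`cowgait` analyses side-view keypoint trajectories of walking cows.
Coordinates are in a camera-calibrated sagittal plane: `x` is the walking
direction (cm, increasing), `y` is height above ground (cm), time is
`frame / fps`. Eight keypoints are tracked: head, withers, mid-back,
tailhead and the four hooves (FL/FR front, HL/HR hind). Keypoint CSVs are
long-format (`cow_id, frame, keypoint, x_cm, y_cm`) with 0-based frames
and blank cells for occluded observations. Pose estimation itself is out
of scope: trajectories enter the package already tracked.

Occluded frames are filled by linear interpolation from adjacent frames
(nearest-value fill at clip edges); a keypoint observed in fewer than two
frames is unrecoverable and rejected.

## Feature definitions and numerical choices

* **Back arch** — curvature `k = 1/R` of the circumcircle through
  withers, mid-back and tailhead, computed as `4·Area/(abc)` so collinear
  points give exactly 0. The per-cow feature is the per-frame curvature
  averaged over frames in which at least one hoof is in stance; whether a
  single posture, mean or maximum is most informative is genuinely open,
  and the mean was chosen as the least noise-sensitive option.
* **Head bob** — the head-height series is linearly detrended; a "swing"
  spans successive *upward* zero-crossings (one full cycle containing one
  peak and one trough), and the feature is the maximum peak-to-trough
  excursion over swings, with parabolic refinement of sampled extrema.
  Defining a swing as a half-cycle would systematically halve the
  recovered amplitude. Maximising over swings (rather than averaging)
  lets the lameness-affected steps dominate; 0 is returned when no
  complete cycle exists.
* **Speed** — net withers displacement over elapsed time.
* **Gait events** — a frame belongs to stance when hoof height is below
  1.5 cm *and* per-frame horizontal displacement is below 0.5 cm (the
  smaller of backward/forward differences, so one boundary frame cannot
  split a run); dropout gaps shorter than 2 frames are bridged and runs
  shorter than 100 ms discarded. All thresholds are configurable
  (`ExtractionConfig`); events are quantised to the frame grid (20 ms at
  50 fps). Intervals touching the clip boundary are flagged as censored:
  their touch-down position is still valid, but duration-based features
  skip them and stride counting never anchors on a censored touch-down.
* **Step overlap** — per hind touch-down, the signed distance from the
  most recent same-side front print; per-side values are averaged over
  cycles and the signed maximum of the two sides is the feature
  (positive = under-tracking). Aggregation across cycles is not fixed by
  the underlying definition; mean-then-max was chosen.
* **Supporting phase** — mean stance duration per hoof, then the maximum
  contralateral difference (front pair vs hind pair). The raw per-hoof
  stance duration is exposed via `StanceInterval`; the *asymmetry* is the
  lameness feature, since a cow unloads the painful limb.
* **Hoof step time** — per hoof, consecutive touch-downs define stride
  cycles; each pair of consecutive cycles sums to a two-stride duration,
  the per-hoof value is the mean of those sums, and the feature is the
  maximum across hooves.

Units throughout: curvature cm⁻¹, lengths cm, times ms, speed m/s.

## Synthetic cohorts

No real recordings ship with the package, so the generator is the test
bed. It has two layers.

**Feature-level cohorts.** Per locomotion score *s*, features are drawn
around fixed per-score population means (defaults: the published
Table of per-score averages — e.g. sound cows walk 2.2 m/s with a
2.7×10⁻⁴ cm⁻¹ back arch; severely lame cows show 17.3 cm step overlap and
318 ms stance asymmetry) with:

* lognormal class-conditional distributions (features are positive and
  right-skewed) except step overlap, which is normal because sound cows
  straddle zero (over- vs under-tracking);
* a per-cow latent "expressiveness" effect shared across features
  (`cow_effect_sd = 0.5`, i.e. half the class SD) plus residual
  equicorrelation so that any two features correlate at
  `cross_feature_corr = 0.3` within a class — this is the individual
  variability that motivates multi-feature detection;
* per-score coefficients of variation (3×6 table) calibrated once to the
  reported distributional structure: pairs of scores described as
  *separated* have disjoint interquartile ranges, *overlapping* pairs
  share central-95% mass, and back-arch spreads follow the reported
  quartiles (score-3 IQR ≈ 0.0009–0.0011 cm⁻¹ ⇒ CV ≈ 0.15). Defaults:
  back arch (0.30, 0.30, 0.15), head bob 0.30, speed 0.25, supporting
  phase 0.30, hoof step time 0.55, step-overlap SD (3, 4, 6) cm. The
  hoof-step-time CV must exceed ≈0.5 for all three scores to overlap
  given the 821.6→1576.9 ms mean span; the source figures are not fully
  mutually consistent here (the step-overlap plot also centres score 1
  near −2.5 cm while its table mean is +0.8 cm), and the generator
  follows the tabulated means.

Default composition is 80/66/29 cows for scores 1/2/3 (175 total),
mirroring the reference cohort's imbalance.

**Trajectory level.** `sample_gait_parameters` maps a feature draw to
mechanistic `GaitParams` whose closed-form implied features equal the
draw, after clipping to realisable gaits (stride period 250–1500 ms so a
5–10 s clip covers ≥3 cycles; stance ≥120 ms; asymmetry bounded by the
stance time available; speed 0.5–5 m/s; |step overlap| ≤ 40 cm). The
stride period is shared by all four hooves — sustained per-hoof period
differences would make the hooves drift apart — so the two-stride feature
is 2× the period. `synthesize_trajectory` then renders frames at exactly
`fps`: withers advance at constant speed; the head oscillates at stride
frequency with the configured peak-to-trough amplitude; the three back
keypoints ride on a circular arc of the configured curvature (mid-back
raised by the sagitta of a 90 cm chord); hooves follow the bovine walk
footfall sequence LH–LF–RH–RF, holding position at height 0 during stance
and advancing one stride during swing (smoothstep in `x`; in `y` a sine
arc on a 2 cm clearance floor, since a real toe leaves the ground
abruptly at lift-off — this keeps detected events within one frame of
ground truth). Ground-truth events and implied features are returned with
the trajectory; an optional dropout rate (default 2% in the pipeline)
blanks keypoints to exercise interpolation.

What the generator does *not* emulate: tracking noise and jitter, camera
perspective error, within-bout speed changes, stopping or turning cows,
herd-level covariates (parity, body condition), and any pixel-level
appearance. Passing tests therefore validate the formulas, the event
logic and the statistical machinery — not robustness to real tracking
artefacts.

## Classification protocol

Stratified k-fold CV (default k = 5) preserves the 80/66/29 class ratio
in every fold; a class smaller than k is rejected. Within each fold,
features are standardised with training-fold statistics only (population
SD; zero-variance columns pass through centred with a warning) — the
held-out block is never used for normalisation. Classifiers: linear SVM
(`LinearSVC`, primal L2, one-vs-rest), decision tree (entropy criterion,
minimum leaf 2, seeded tie-breaking), multinomial logistic regression;
the L2 penalty strength (C) defaults to 1.0 and is configurable. Class
imbalance is handled by stratification alone — no resampling or class
weights — matching the comparative design this package reproduces.

Metrics come from one-vs-rest reduction of the 3×3 confusion matrix:
sensitivity (= recall), specificity, precision, per-class F1 and
Macro-F1. Because the binary accuracy formula has no unique multiclass
extension, reports carry both the overall accuracy (trace/total, the
primary number) and the macro-average of per-class one-vs-rest
accuracies. Ratios with zero denominators are 0 by convention.

Feature importance is weight-based: per fold, on standardised training
data, mean |coefficient| per feature across the per-class linear machines
(impurity importance for the tree), averaged over folds. Whether raw or
absolute coefficients, and which multiclass decomposition, best matches
the original analysis is unknowable from the outside; the convention here
is declared, not numerically matched.

The hierarchical cascade trains, per fold, a linear SVM on back arch
alone (severe vs rest) and a second linear SVM on step overlap +
supporting phase using only the *true* non-severe training cows; at test
time stage-2 sees exactly the stage-1 negatives, and combined predictions
are pooled as a three-class problem. Stage-wise binary reports evaluate
stage 2 on the stage-1 negatives whose true score is 1 or 2 (a missed
severe cow has no sound-vs-mild truth).

## Problem sizes and determinism

Every stochastic component takes a seed (cohort draws, fold shuffling,
tree tie-breaks, dropout), and identical config + seed reproduces
byte-identical cohorts and reports. The shipped analyses use the cohort
sizes of the emulated study (175 cows; 2000 per score for mean
calibration; 20 cohort seeds for the comparative battery; 50 random gaits
for recovery checks), which keep the full test suite and the acceptance
script in the tens-of-seconds range.

## Known limitations

* The reference study's real-data accuracy tables cannot be reproduced
  numerically — its dataset was never deposited — so classification
  checks are structural (which design wins, which features dominate),
  not value-matching.
* Back arch uses three collinear-prone keypoints; with real tracking
  noise the curvature of a nearly flat back is poorly conditioned, and a
  smoothing step (out of scope here) would be advisable.
* Event detection assumes a calibrated ground line (`y = 0`); sloped or
  cluttered floors would need a per-clip ground-plane fit.
* The cascade's stage-1 threshold inherits the class imbalance of the
  cohort; with very few severe cows per fold its recall is noisy.
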