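# Methods

## Problem setting and model

A transverse CT slice of a lung brachytherapy patient shows each implanted
18-gauge needle as a thin (~1.3 mm), bright, straight segment. Needles are
inserted through a coplanar template, slices are ~5 mm thick and aligned so
each needle lies in-plane, needles do not bend, and the number of needles
per slice is known. Under these assumptions per-slice needle segmentation
reduces to: (1) select candidate needle pixels, (2) robustly fit one 2D
line per needle, (3) find each tip along its axis.

All geometry is computed in millimetres. Pixel (row, col) with spacing
(s_y, s_x) maps to (x, y) = (col·s_x, row·s_y), 0-based, pixel-centre
convention. A needle axis is an undirected line (anchor + unit direction,
sign-normalised); direction (entry vs tip) is only assigned during tip
localisation.

## Preprocessing

* **ROI**: the axis-aligned bounding box of the physician's target contour,
  expanded by `margin_mm` (default 3 mm, converted per axis and rounded
  outward) and clipped to the image. An expansion helper grows the box in
  fixed steps if supplied candidates fall outside it.
* **Contrast**: saturating power-law map with input window
  [i_low_in, i_high_in] = [0.15, 1.0], output span [0, 1] and γ = 2
  (γ > 1 compresses the background and stretches the bright shaft; the
  exact value is empirical and config-exposed). Intensities are per-slice
  min-max normalised at load time (an optional fixed HU window is
  available for DICOM input).
* **Thresholding**: candidate pixels are those with enhanced intensity
  ≥ α (default 0.85, empirical, config-exposed); their centre coordinates
  (mm) and intensities form the candidate PointSet.

## Robust axis estimation

**Scale.** The core robust scale is σ = 1.4826·(1 + 5/(n−m))·med|dᵢ|, the
MAD-type scale with a small-sample correction, valid for n ≥ 2m. Because
the pipeline knows the outlier ratio ε analytically (see successive
deletion) and must operate up to ε = 0.8 — beyond the median's 50%
breakdown — the scoring scale replaces the median with the (1−ε)/2 quantile
of |dᵢ|: the median of the presumed-inlier fraction. At ε = 0 the two
coincide. Inliers are classified once per model with the gate d ≤ 1.96σ.

**Selection.** Candidate two-point models are ranked by *minimum* robust
scale (least quantile of residuals), with support then iteration order as
tie-breaks. Support counted under a per-model scale is not comparable
between models — a bad model inflates its own σ, hence its gate and its
support, so maximising that support selects sloppy models; minimising the
robust scale is the selection criterion native to this scale estimator and
behaves continuously from clean data to heavy contamination.

**Pretest.** Before full verification, each hypothesis is scored on a
fresh random subset of n = 15 points drawn without replacement; it is
rejected if fewer than n_f subset points fall inside the current best
model's gate. n_f is the largest value whose binomial pass probability
Pt = P(Bin(n, 1−ε) ≥ n_f) stays at or above 0.80, so a correct model
survives with probability ≥ 0.80 while grossly wrong models rarely do.
The iteration budget is enlarged accordingly to
k ≥ log(1−P)/log(1−(1−ε)²·Pt), P = 0.99. The subset gate must be
model-independent (a gate derived from the same subset's own residuals
always covers half the subset and never rejects anything), so the first
three candidates are fully verified to bootstrap it.

**Local optimisation.** The winner seeds a local stage: k_L = 15 two-point
resamples drawn inside its consensus, ranked by the median robust scale of
the consensus residuals; then the best model is refined by alternating
(gate on all N points with the quantile scale) → (total-least-squares PCA
fit of the gated set) until the consensus is stable, at most 10 rounds.
Computing the gate quantile on *all* N residuals at every round keeps the
iteration from contracting to zero (re-quantiling a truncated set shrinks
geometrically). The refinement is accepted only if it improves the robust
scale on the full dataset; otherwise the seed result is returned with a
warning flag.

**Residual-risk guard.** The sampling budget leaves a 1−P chance that no
clean pair is ever drawn (measured ≈ 0.5% per run at ε = 0.8), in which
case the winner is a noise-cluster artefact. Such fits betray themselves:
their consensus is either not needle-shaped (principal-variance ratio
below 50) or holds > 1.2× the (1−ε)N points a correct model can have.
Either symptom triggers a fresh seeded sampling round (≤ 3 restarts),
keeping the best robust scale across attempts; verification counters sum
over attempts. A false alarm costs one extra round and returns the same
fit. The plain baseline estimator is left unguarded on purpose: it is the
degradation reference (no pretest, no local optimisation, k from the
classical bound).

**Raster data.** Candidate sets derived from images have residuals
quantised to the pixel grid — a diagonal of pixel centres is *exactly*
collinear, which would collapse the quantile scale to zero and gate a
single grid row. The pipeline therefore floors the scale so the gate spans
at least 0.6 pixel diagonals.

**Determinism.** Every estimator is a pure function of (data, config,
seed). One `numpy` Generator is threaded through a detection; per
iteration the stream order is (minimal-sample draw, with redraws for pairs
closer than 0.35 mm) then (pretest subset draw), then local-stage draws.

## Multi-needle extraction and tips

With N₀ initial candidates, noise fraction ε_noise (default 0.15) and a
known needle count, the expected per-needle support is
n_en = ⌊N₀(1−ε_noise)/n_needles⌋ and the round-j outlier ratio is
ε_j = (N_j − n_en)/N_j, recomputed from the live count N_j before every
round (clamped to 0 with a warning if the pool depletes). A round's model
is accepted if its support reaches `accept_frac`·n_en (default 0.5 — the
stop rule "no subset satisfies the model conditions" is not otherwise
quantified); its inliers are then deleted. Rounds stop at the needle
count, on a rejected model, or when fewer points remain than the pretest
needs; fewer detections than needles is a valid outcome.

Tips: the image intensity is sampled along the fitted axis across the ROI
(bilinear, step = half the smaller pixel spacing). Samples at or above a
threshold *T* form runs; runs shorter than `min_run` = 3 samples are
discarded as isolated bright noise. The profile is oriented so the bright
run begins nearer the entry side (configurable insertion edge, or
automatic), the distal end of the last surviving run is the tip, and the
exact crossing is interpolated between the last two samples to remove the
sampling-step quantisation. *T* is the density-crossing point of Gaussian
fits to needle and background intensity samples (equal-variance case: the
midpoint of the means); by default it is trained per slice using the
candidate pixels as known needle positions and the sub-threshold ROI
pixels as background, with a fixed-T override in the config. If no run
survives, the tip falls back to the extreme projections of the inliers
onto the axis and the detection is flagged.

Known bias: on a shaft of width w the profile crossing sits on the rounded
tip cap, ~w/2·(scaled by T) beyond the geometric endpoint, so tip errors
have a ~0.3–0.6 mm floor largely independent of insertion depth.

## Synthetic data

**Planted lines** (the simulation design): 1500 points; a 90 mm segment
through the centre of a 100 × 100 mm field at a seed-random orientation;
round((1−ε)·n) inliers uniform along the segment with perpendicular
Gaussian jitter σ = 0.5 mm; outliers assigned to 6 Gaussian clusters
(σ = 6 mm) with uniform-random centres, truncated to the field by redraw
(never by projection, which would plant spurious straight boundary
lines). The outlier spatial law and jitter are this package's declarations
— the original study conditions specify only the dataset size, the ratio
range and Gaussian noise.

**Phantom slices**: needles rendered as anti-aliased bright segments
(width 1.3 mm, intensity 1.0 — metal saturates the per-slice window — on a
0.2 background), entries along the top edge, angles 0–60°, depths
40–100 mm, 0.7 × 0.7 mm pixels, additive Gaussian noise (σ = 0.03) and
optional streak artifacts; exact axes and tips returned as ground truth;
overlapping shafts are an error.

**What passing these tests shows — and does not.** The generators exercise
contamination robustness, the pretest economics, successive deletion and
tip logic under controlled truth. They do not model CT physics: no partial
volume, beam hardening, realistic metal-artifact structure, rib clutter or
patient anatomy. Axis accuracy on the clean rendered shaft is therefore
5–30× better than on real phantom CT, and the tip-error floor is the cap
bias above, not image noise. In particular, the depth dependence of the
tip error seen on physical phantoms (driven by degree-scale axis errors at
shallow insertion) does not reproduce here: axis errors shrink with depth
as expected, but tip errors are depth-flat at the ~0.5 mm floor. Real-data
performance must be validated on real slices.

## Numerical choices and degenerate inputs

σ = 0 gates only points within 1e-9 mm of the line. Two-point samples
closer than 0.35 mm (~0.5 px) are redrawn without consuming budget; if
every sample is degenerate the estimator raises. PCA on coincident points
raises; an exactly isotropic cloud breaks the tie toward the x-axis.
Angular deviation folds with |cos| so opposite direction signs compare as
near-zero, and equality of lines is testable via sign-normalised
directions. `min_samples` returns 1 when (1−ε)^m·Pt ≥ 1. Depleted
multi-needle pools clamp ε to 0 with a warning. Empty candidate sets yield
an empty detection list, not an error.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| P | 0.99 | sampling confidence |
| ε | supplied / 0.5 | outlier ratio (pipeline: from ε_j) |
| n | 15 | pretest subset size |
| Pt_min | 0.80 | minimum pretest pass probability |
| k_L | 15 | local resamples (10–20 sensible) |
| z | 1.96 | inlier gate multiple of σ |
| ε_noise | 0.15 | candidate noise fraction |
| margin | 3 mm | ROI expansion |
| γ / α | 2 / 0.85 | contrast exponent / candidate threshold (empirical) |
| accept_frac | 0.5 | per-round support acceptance vs n_en |
| min_run | 3 samples | minimum tip plateau length |

## Run sizes

The simulation sweep (8 ratios × 15 repetitions × 1500 points, both
estimators) completes in a few seconds on one CPU; the phantom grids used
in the tests (10 seeds per condition) take well under a minute. These are
the full study sizes, not reductions.
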