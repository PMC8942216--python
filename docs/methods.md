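# Methods

This note records the models, parameter choices and numerical decisions
behind `woundmetry`, and what the synthetic phantoms do and do not
establish about behaviour on real photographs.

## Measurement model

The only physical quantity the pipeline trusts is the splint's inner
diameter (default 10 mm; outer 16 mm). Everything else is a pixel count.
With `A_in = π(d_in/2)²` and `R = wound_px / splint_inner_px` measured in
the same crop, the wound area is `A_u = A_in · R`. Both counts carry the
same unknown mm-per-pixel factor, so the estimate is invariant to camera
distance; the test suite verifies invariance under ±20 % scale changes to
within 2 % (the residual is boundary rasterization).

The splint-inner count is the *full filled disk* bounded by the inner
circle, including the wound it encloses. An alternative convention
(counting only skin inside the ring) rescales all areas by a common factor
and would cancel in closure percentages; the convention is stated here so
external annotations can be adapted consistently. Wound pixels are not
clipped to the inner disk by default (satellite-free crops make this moot;
clipping would silently hide detection errors).

Closure is computed on areas, not raw counts, so splint imputation runs
*before* closure: `C_P(i) = 100 − 100·A_i/A_0`. Day 0 must exist (after
temporal filling) with positive area, otherwise the series errors out
rather than guessing a baseline.

## Mask cleanup

Score maps are 8-bit; thresholds are wound ≥ 20 and splint ≥ 40
(inclusive on equality — the comparison direction is unspecified in the
underlying recipe, and inclusivity makes the threshold value itself
meaningful). The splint keeps its largest connected component; the wound
keeps the component nearest the crop centre among those strictly larger
than 50 px (small wounds are below the annotation floor). Connectivity is
8 by default. Centroid selection is pure arg-min over distance; an
optional maximum-distance cutoff exists in principle but is deliberately
not imposed, since the arg-min already rejects peripheral satellite
wounds whenever a central wound is present.

Two floors extend the published constants:

* `min_splint_size` (50 px): a largest-component rule with no floor will
  happily promote a few pixels of boundary speckle to "the splint" on
  splint-less frames, which then calibrates absurd areas. Any real inner
  disk is ≥ ~10³ px at every supported scale, so 50 px only rejects noise.
* the classical reference segmenter only emits an inner-disk region when
  silicone-ring pixels are actually visible (see below).

## Imputation of missing splints

Technique "mean" assigns every splint-less record the arithmetic mean of
all detected splint pixel counts. Technique "nearest" assigns the splint
count of the record whose *wound* pixel count is closest; ties break
toward the nearest day, then the lexicographically smallest wound id
(the underlying pseudocode specifies no tie rule). Interior days with no
measurement at all take the mean of their nearest measured neighbours,
applied left-to-right across runs of gaps; leading/trailing gaps copy the
nearest measured value.

**When "nearest" helps, and when it does not.** Size-matched imputation
exists for heterogeneous camera distance: two frames showing
similar-sized wound images were probably shot at similar distance, so the
donor's splint count transfers. Our simulations confirm this in the
regime where camera scale is the dominant source of pixel-count variation
(slowly-healing phase, ±20 % scale jitter): nearest roughly halves the
cohort-curve deviation relative to the mean technique (≈4 vs ≈8
percentage points at 50 % removal, 20 seeds). When healing-stage
variation dominates instead — wounds shrinking several-fold across the
series — wound size confounds stage with scale, and the two techniques
perform equivalently (mean can even look better on the *cohort mean*
curve because its errors partially cancel across wounds). Both remain
within 10 points of baseline at 50 % removal under the default cohort.

## The phantom generator

Phantoms emulate the study layout: two wounds ("L"/"R") per mouse, one
frame per wound per day over 16 days. Each wound draws healing parameters
once: initial diameter ~N(6, 0.3) mm clipped to [5, 7]; closure day
U(12, 16); early expansion peak U(1.05, 1.3) reached at U(1, 3) days.
The open-area fraction is exactly 1 at day 0, rises linearly to the
expansion peak, then decays along a fixed-shape exponential ramp
`expm1(k(1−u))/expm1(k)` (k = 2) hitting exactly 0 at the closure day.
The curve family is invented plumbing — published studies show such
curves without parametrizing them — chosen to be monotone after the peak
and recoverable from two knots. Per-scene multiplicative area noise
(σ = 0.02) models biological and measurement day-to-day variation.

Rendering uses flat palette colours (skin, erythematous inner skin, dark
wound, near-white silicone, grey occluder) with no texture. The wound
boundary is perturbed by radial Fourier modes (orders 2–3, total
amplitude ≤ 5 % of radius by default, ≤ 15 % supported), which keeps the
analytic disk area valid to well under 1 %. The mm-per-pixel scale
defaults to 0.05 and is jittered ±20 % per scene to emulate camera
distance — the nuisance the calibration formula must cancel; the pipeline
never sees the scale. Corruptions (lighting gain 0.85–1.15, blur σ ≤ 2,
occlusion, satellite wounds, wound-coloured false blobs, landscape
orientation, missing splints) are applied to the *image only*; masks
remain exact ground truth. Missing-splint patterns are either an exact
random fraction of scenes or an 8-day window of days.

What phantoms do not emulate: skin texture and fur, specular highlights,
perspective/angle distortion, deformed or partially torn splints, and
annotation ambiguity at the wound margin. Passing tests therefore
demonstrate the correctness and robustness of the *measurement machinery*
(detection → cleanup → calibration → imputation → closure), not
segmentation accuracy on real tissue.

## Segmentation backends

The deterministic reference backend classifies pixels against the
generator palette in two passes: a chromaticity pass (gain-invariant)
identifies background skin, from which a global lighting gain is
estimated as a median brightness ratio; classification then runs in
gain-normalized linear RGB, where resampling and blur mix colours
linearly, so boundary pixels split evenly between their two classes
instead of favouring the brighter one. The inner-disk channel is the
inner-skin class with holes filled — and is emitted only when ring-class
pixels are visible, because on splint-less frames the thin wound/skin
mixing band closes into a ring that hole-filling would otherwise promote
to a fake inner disk. The backend is exact on uncorrupted phantoms, and
intentionally loses occluded pixels (occlusion robustness is the
post-processing stages' job, not the classifier's).

The trainable backend is a two-level encoder-decoder with skip
connections, ~8 base channels, and two *independent* sigmoid output
channels — wound and splint-inner overlap (the wound lies inside the
disk), so softmax classes would wrongly compete. It is implemented
directly in NumPy (im2col convolutions, explicit backpropagation, Adam at
3·10⁻³), trained with soft dice loss (smoothing constant 1, classes
equally weighted) under the augmentation recipe above; masks use
nearest-neighbour resampling and images bilinear with edge reflection.
Desk-scale defaults — 30 epochs, batch 4, 64 px phantom frames — train in
under a minute on one CPU and reach ≈0.95 post-processed dice on held-out
phantom series; the full-scale recipe (1000 epochs, 352 px crops) is
configuration, not default. Training splits by whole wound series, never
by frame, and refuses leaky or empty splits.

## Numerical choices and degenerate inputs

* Orientation: landscape frames rotate 90° counter-clockwise (any fixed
  direction works; downstream stages are rotation-agnostic).
* Down-sampling: exact 2×2 area averaging, odd edges floored away,
  ties-to-even rounding (a 0/255 checkerboard block becomes 128).
* Cropping: window translated minimally into large images; symmetric
  zero padding for images smaller than the crop; total function with
  provenance, never an error.
* Polygon fill: pixel-centre even-odd rule, origin at the top-left
  corner, pixel (r, c) centred at (c+0.5, r+0.5); verified against an
  exhaustive per-pixel oracle. Mask→polygon→mask round trips are exact up
  to the one-pixel contour band.
* Component ties: equal-size components resolve to the earliest pixel in
  scan order; equal centroid distances to the lower label.
* Detection confidence ties keep the first detection listed.
* Empty detections, zero splint pixels, and all-missing splints are
  signals (`None` / typed exceptions), not crashes, so one bad frame
  costs one day, never a run.

## Known limitations

* Hard binary counting at half resolution has a boundary-band
  discretization bias of order one pixel of perimeter; it is
  multiplicative and largely cancels in closure ratios, but its
  radius dependence leaks ~2 pp into closure at coarse scales (wounds
  only tens of pixels across). Work at native resolutions comparable to
  the defaults (inner ring ≥ ~100 px across) for sub-point accuracy.
* The Hough circle detector assumes the splint's circular edge is the
  dominant circle in the frame; it has no wound-specific appearance
  model and returns nothing for splint-less frames (use the trained
  detector pathway or external detections there).
* The reference segmenter is tied to the generator palette by design; it
  is a test instrument, not a claim about real images.
* Training determinism holds for single-threaded BLAS; thread-level
  reduction reordering can perturb the last float bits across machines.
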