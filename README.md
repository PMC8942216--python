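# woundmetry

Automatic wound detection and size estimation for photographs of splinted
excisional wounds.

Splinted-wound studies (the standard murine wound-healing model) photograph
each wound daily for ~16 days. Estimating wound area from those photographs
is slow, subjective manual work, and the photographs themselves are messy:
camera distance and angle drift, frames arrive in a landscape/portrait mix,
lighting changes, tape or regrown hair occludes the wound, several wounds
appear in one frame, and the reference object is missing or damaged in a
substantial fraction of images. `woundmetry` implements a measurement
pipeline that is robust to all of these, for researchers who want closure
curves out of ordinary camera or phone images.

## Method

The pipeline runs six stages per image:

1. **Preprocess** — rotate landscape frames to portrait (lossless 90°) and
   down-sample to half resolution by area averaging.
2. **Detect** — locate the wound of interest. Detection backends are
   pluggable (`image -> [Detection]` in normalized midpoint coordinates);
   the package ships a ground-truth oracle for synthetic data and a
   classical Hough circular-edge detector that finds the splint ring.
   When several wounds are detected, the highest-confidence one wins.
3. **Crop** — an exactly 352×352 window about the detected midpoint,
   translated (or zero-padded) to stay inside the frame, with provenance
   for mapping crop pixels back to source coordinates.
4. **Segment** — per-class 8-bit score maps for the wound and the splint's
   inner disk. Backends: a compact U-Net-style encoder-decoder (NumPy,
   two resolution levels, skip connections, two independent sigmoid heads)
   trained with a soft dice loss under on-the-fly augmentation (flips 50 %,
   rotation ±90°, linear contrast `127 + α(v−127)` with α ∈ [0.5, 1.5],
   intensity ×[0.5, 1.5], Gaussian blur 35 % with σ ∈ [0, 6]); or a
   deterministic palette classifier that is exact on clean phantoms.
5. **Post-process** — threshold the maps (wound ≥ 20, splint ≥ 40 of 255),
   keep the splint's largest connected component, keep the wound component
   nearest the crop centre among those larger than 50 px; impute missing
   splint measurements from the cohort mean or from the closest-sized
   splinted wound; fill missing days by neighbour averaging.
6. **Measure** — the splint's inner circle has a known diameter
   (10 mm by default), so with `A_in = π(d/2)²` and `R` the ratio of wound
   to splint-inner pixel counts,

   &nbsp;&nbsp;&nbsp;&nbsp;`A_u = A_in · R`  (area, mm²)

   which cancels the unknown mm-per-pixel scale, and

   &nbsp;&nbsp;&nbsp;&nbsp;`C_P = 100 − (A_i / A_0) · 100`  (closure, %)

   giving 0 % at day 0, 100 % at full closure, and negative values during
   early wound expansion.

Because the real imaging data is not required for development or testing,
the package includes a synthetic **phantom generator**: circular ~6 mm
wounds with irregular (radial-Fourier) boundaries inside 10/16 mm annular
splints, rendered over a 16-day healing trajectory with per-scene camera
scale jitter, lighting gain, blur, occlusion, satellite wounds, false
wound-like blobs, and configurable missing-splint patterns — all with
pixel-exact ground-truth masks.

## Worked example

```
woundmetry simulate --n-mice 2 --n-days 8 --out cohort --seed 42 --missing-fraction 0.25
woundmetry run --input cohort --out results --detector oracle --segmenter reference --imputation nearest
cat results/cohort_summary.csv
```

prints

```
day,mean_closure_pct,n_wounds
0,0.00,4
1,3.95,4
2,6.65,4
3,2.66,4
4,18.80,4
5,36.35,4
6,42.96,4
7,58.76,4
```

the per-day cohort mean closure percentage over the four simulated wounds:
0 % at day 0 by definition, a dip toward negative values while wounds
expand early, then rising closure as they heal. The per-wound table
`results/series.csv` holds the underlying records, e.g.

```
wound_id,day,wound_px,splint_px,area_mm2,closure_pct,splint_imputed,timepoint_filled
C1-M1-L,0,4095,11400.0000,28.2123,0.00,False,False
C1-M1-L,1,1704,5487.0000,24.3907,13.55,False,False
C1-M1-L,2,2416,10338.0000,18.3548,34.94,True,False
```

Day 0 reads 28.2 mm² — a 6 mm wound (π·3² ≈ 28.3 mm²) recovered without
knowing the image scale. Day 2's splint was missing in the input (25 % of
frames are, by construction); its `splint_px` was imputed from the
closest-sized splinted wound (`splint_imputed=True`) and the area
calibrated through it.

Other entry points: `woundmetry train` fits the segmenter on a simulated
cohort and writes a checkpoint (+ per-epoch loss/IoU log);
`woundmetry evaluate` runs the splint-removal robustness experiment
(random-fraction or day-window removal patterns) against a measured
records table and reports the mean/max deviation of the cohort closure
curve in percentage points.

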