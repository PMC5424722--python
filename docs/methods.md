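# Methods

This note documents the models, parameter choices and numerical
conventions behind `thermoseed`, and what the phantom-based tests do
and do not establish about real data.

## Thermal model and calibration

Thermal frames are 8-bit grayscale rasters whose gray values encode
temperature linearly over a preset window: gray 0 ↔ `t_min_c`, gray
255 ↔ `t_max_c` (defaults 21 °C and 27 °C). One gray step is
`(t_max − t_min)/255 ≈ 0.0235 °C`; no sub-step information survives
quantization, which bounds everything downstream. An audit mode
(`ThermalCalibration(span_only=True)`) reproduces a zero-based variant
of the mapping that omits the `t_min_c` intercept; relative
temperatures are identical in both modes because the intercept cancels
in the seed-minus-environment difference.

The relative temperature `rT = T_seed − T_env` is the core measurand.
Subtracting the local filter-paper temperature cancels, by
construction, every additive disturbance common to seed and paper:
incubator drift, evaporative cooling of the wet paper, and any global
gray offset of a frame (shift invariance is a tested property).
Saturated pixels (gray 0 or 255) are included in region means but
counted; a disk saturation fraction above 5 % triggers a warning since
clipped values bias the mean toward the window edge.

## Seed regions

Segmentation runs once on the first visible frame — seeds do not move
during a germination test — and the masks are reused for all frames.

* **Background subtraction.** The illumination field is estimated by a
  grey opening with a window wider than any seed
  (`background_radius_px`, default 2.5 × expected seed radius): smooth
  brightness gradients pass into the background model, compact bright
  objects do not. A second, small opening (`blob_radius_px`, default
  4 px) then removes bright features narrower than a seed — specular
  reflection points on the wet paper. The corrected image is clipped
  at zero.
* **Edge extraction + region growing.** Canny edges (hysteresis
  thresholds 4/10 on the corrected image, σ = 2) act as growth
  barriers; regions grow by flood fill from interior brightness maxima
  with an intensity tolerance (default 55 gray). Because the edge ring
  itself is withheld from growth, accepted regions are dilated by
  `region_dilation_px` (default 2 px, matching the Canny σ) to recover
  the seed boundary; without this the mask underestimates seed area by
  ~15 % and the environment annulus can creep onto the seed's thermal
  footprint. An area gate (defaults 0.3–1.8 × the expected seed area)
  rejects fragments and fused seed pairs — two seeds joined by a
  bridge are excluded rather than silently accepted as one region.
* **Disk and annulus.** The measurement disk is centered on the mask
  centroid with radius `sqrt(area/(3π))`, i.e. one third of the seed
  area, avoiding the thermally mixed seed rim. The environment annulus
  spans 1.2–1.6 equivalent radii around the centroid, minus every seed
  mask: close enough to track the local paper temperature, far enough
  to exclude the seed's own halo. Both are mapped into thermal pixels
  through the affine registration transform (pixel centers mapped,
  rounded, deduplicated). Coordinates are (row, col), 0-based.

## Curve parameters

Curves are smoothed by a centered moving average (default 5 frames =
25 min; edges use truncated windows) before landmark extraction.

* **Imbibition window.** Extrema and drop detection are restricted to
  the first `search_window_min` (default 300 min). Over five days the
  slow post-minimum plateau can drift below the imbibition minimum, so
  global extrema would stop describing the water-uptake kinetics that
  carry the viability signal. Reported landmark times on the reference
  cohort (≈ 15–49 in tabulated units) are consistent with frame
  indices at the 5-min cadence, i.e. ≈ 75–245 min, inside this window.
* **Sharp-decline onset.** `trT_drop` is the earliest time whose
  discrete forward derivative stays strictly below −θ for k
  consecutive frames (θ = 0.005 °C/min, k = 3). A slope of exactly −θ
  does not qualify. If no run qualifies (flat curves), the drop fields
  are imputed with the window-end time and value for classification,
  and the imputation is logged.
* **Ties** at equal extremum values resolve to the earliest time, with
  a 1e-9 relative tolerance absorbing moving-average round-off.
* **Fixed-time values** `rT_0h … rT_120h` are smoothed values at the
  grid point nearest each 20-hour mark. A mark is covered if the grid
  reaches within one frame interval of it: the standard 1440-frame run
  (t = 0, 5, …, 7195 min) ends one frame shy of the 120 h mark, which
  is then read at 7195 min. Frames after the 120 h mark never
  influence any feature.
* **Early vector.** The 19 raw (unsmoothed) rT values at t = 0, 10,
  …, 180 min feed the early-decision classifier; the frame grid must
  align with the 10-min marks.

## Group statistics

Per-parameter group summaries use the sample SD (n − 1). Fisher LSD
comparisons use the pooled ANOVA error mean square with the pairwise
standard error `sqrt(MS_e (1/n_i + 1/n_j))` — the textbook equal-n
form `sqrt(2 MS_e/n)` is available via `equal_n_mode`, which
substitutes the harmonic mean of the group sizes and agrees exactly
when sizes are equal. p-values are two-tailed from t with
`df_e = N − k`; 95 % CIs use the same critical value. No family-wise
correction is applied beyond the LSD procedure itself; with three
groups this is the classic protected-LSD setting, and the null
calibration test verifies the per-pair false-positive rate sits at the
nominal α = 0.05.

The published multiple-comparison table for the reference cohort is
reproduced at the level of mean differences only. Its standard errors
imply a t-multiplier (~2.026, df ≈ 37) inconsistent with group sizes
41/32/47 under any LSD formula, and its viable-group `rT_0h` rows are
inconsistent with the published viable `rT_0h` group mean (they imply
−0.1593 instead of −0.2594); those two rows are excluded from the
acceptance checks and the discrepancy is noted here rather than
patched over.

## Classification

The three pairwise soft-margin SVMs use the standard RBF kernel
`exp(−γ‖x−y‖²)` with C = 2 and γ = 2 (an unsquared Laplacian-like
variant `exp(−‖x−y‖/σ²)` is kept as an audit option,
`KernelSpec(form="unsquared")`). The quadratic programs are solved by
scikit-learn's SVC; the one-vs-one pairing, accuracy-weighted voting,
fold handling and reporting are implemented here. Dual feasibility
(Σ y_i α_i = 0, 0 ≤ α_i ≤ C) is checked after each fit, and the
training-error behaviour is validated against an exhaustive
linear-separator search on tiny 2-D toys.

* **Feature scaling.** The kernel width is fixed by the study design,
  so the feature scale must put typical squared distances at order
  one. Per-column z-scoring does not: in 13–19 dimensions standardized
  points sit at squared distances of ~10–25, `exp(−2d²)` degenerates
  to an identity kernel matrix, and cross-validated accuracy collapses
  toward chance. The default therefore maps each training column onto
  [0, 1] (min–max, the scaling the libsvm practitioners' guide
  recommends), fitted on training rows only and applied unchanged to
  test rows; `scaling="zscore"` and `scaling="none"` remain available.
* **Voting.** Each binary model votes for one class with weight
  `p_i / Σ p_j`, where `p_i` is its resubstitution accuracy on its own
  two-class training subset. Equal accuracies give uniform weights,
  reducing the scheme to plain majority voting. Ties in the weight
  sums are broken by the larger accumulated |decision value| among the
  tied classes, then by fixed class order (viable < aged <
  non-viable); the tie rule is an implementation convention.
* **Cross-validation.** Random, non-stratified assignment into k
  near-equal folds (per-fold class counts therefore vary, as they do
  in practice); a draw that leaves any training split without all
  three classes is redrawn and logged. A stratified option exists.
  Identical seeds give identical folds, predictions and reports.

## Phantom generator

The phantom emulates the assay geometry: a tray grid of bright convex
seeds (filled ellipses, gray ≈ 180, with static texture) on darker
filter paper (gray ≈ 60) in the visible channel, optional specular
reflection blobs, and thermal frames built as quantized
`ambient + drift + rT` inside each seed's footprint. Ambient sits at
24 °C with a slow sinusoidal drift within ±0.4 °C (the incubator
tolerance); seed and paper see the same drift, so true rT is
drift-free by construction — a property the round-trip tests exploit.
Gaussian sensor noise (default SD 1 gray) is added before
quantization; out-of-window temperatures are clipped and counted in a
saturation log. Identical scene seeds give bit-identical frames.

Class-conditional rT kinetics follow a landmark parameterization:
eased rise from `rt_start` to an early local maximum `rt_peak`; gentle
dip (15 % of the peak-to-minimum fall — small enough that the pre-drop
slope never reaches the sharp-decline threshold) to the onset
`t_drop`; a front-loaded cubic fall (steep at onset, flattening into
the minimum — the detector should fire at the onset, not mid-fall) to
`rt_min` at `t_min`; a smoothstep rebound (0.2–0.4 °C over 120 min,
fastest in non-viable seeds, encoding the post-inflection warming
ranking); then exponential relaxation toward a long-run plateau.
Default landmarks are the group means reported for a 120-seed pea
cohort, with tabulated times read as frame indices × 5 min; per-seed
jitter SDs are set to one third of the reported group SDs so classes
remain learnable at n = 120. Two synthesis choices depart from the
reported means: the aged start value is lowered to 0.10 °C (the
reported aged start exceeds the reported aged maximum, which is
incompatible with an early-local-maximum shape), and the functional
form between landmarks is ours — no reference curve shapes are
available to fit. Root lengths are uniform within each class band
(viable 1.6–5.0 cm, aged 0.1–1.5 cm, non-viable exactly 0).

**What phantom tests show — and don't.** Passing tests establish that
segmentation, fusion, curve assembly, landmark extraction, statistics
and classification are internally correct and recover known ground
truth through 8-bit quantization, drift and sensor noise. They do not
establish biological validity on real seeds: real seed shapes, wetting
halos, condensation, touching seeds, emissivity variation and
non-Gaussian camera noise are all outside the phantom, and the class
templates inherit the reported landmark statistics rather than an
independent biological model. Classification accuracies measured on
phantom cohorts characterize the pipeline under the stated synthesis
assumptions, not expected field performance.

## Problem sizes and determinism

Desk-scale defaults keep every check cheap: round-trip and
segmentation tests use a 3×2 tray at reduced raster size (300×450 /
120×180) over 6 simulated hours (72 frame pairs); classification
checks use 120-seed cohorts — rendered at 600×900 / 240×320 over the
first 6 hours for the early-decision model, and curve-sampled over the
full 5 days (1440 frames) for the 13-parameter model. All randomness
flows from explicit seeds (`numpy.random.default_rng`); reruns of a
configured experiment reproduce every CSV byte for byte.

## Known limitations

* Registration supports axis-aligned scale + offset only; rotation or
  shear between cameras would need an external rectification step.
* Region growing assumes convex, non-touching seeds; fused pairs are
  excluded (and logged) rather than split by watershed.
* The drop detector is threshold-based; curves whose decline slope
  hovers near θ give onset times sensitive to the smoothing window.
* Pseudo-color thermal exports are out of scope: inputs must be
  grayscale rasters (or raw temperature rasters bypassing the gray
  mapping).
* `p_i` weights default to resubstitution accuracy, which is
  optimistic for small subsets (that is what the voting design
  prescribes); `p_mode="inner_cv"` substitutes a deterministic inner
  3-fold estimate.
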