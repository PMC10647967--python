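# Methods

This note records the models, conventions and numerical choices behind
`as4dpm`, in the spirit of a package-level methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conventions

* All time series share a 0.2 s grid (IR camera sampling = projection
  interval at 1.5°/s and 0.3°).
* Axes: LR positive = patient left; **SI positive = inferior**; AP positive =
  posterior. The inferior-positive SI axis makes the diaphragm, the shroud
  waveform (whose natural sign is "ridge row increases downward") and the
  target SI trace move together on inhalation, so one sign convention serves
  the whole pipeline. The abdominal IR markers move anterior (negative) on
  inhalation, hence end-inhalation is a local *minimum* of the IR trace and
  cycle/phase 0 is anchored there.
* Training window: frames 0–301 (60 s); test window: frames 302–350 (10 s).
  Both are configuration with these defaults.

## Synthetic acquisition model

The simulator is the package's test bed; it emulates the statistical
structure of a free-breathing lung cohort, not any particular patient.

* **Breathing profile**: `A·cos²ⁿ(π φ(t))` with n = 2 by default. The even
  power produces the clinically typical asymmetry — a flat end-exhalation
  plateau and a steep end-inhalation peak. φ advances linearly within each
  cycle; per-cycle periods are drawn from N(3.7 s, 0.3 s) (clipped at 30 % of
  the mean), matching a median breathing cycle of 3.7 s. A random initial
  phase avoids every case starting at end-inhalation.
* **Amplitudes** (peak-to-trough defaults): target LR/SI/AP =
  1.7/11.4/3.3 mm, IR AP = 6.2 mm, four IR markers with individual baselines
  in ±2 mm and independent Gaussian noise (0.1 mm SD). Correlation signs
  default to (−1, +1, −1): LR/AP tumour motion anti-correlated with the
  diaphragm.
* **Drift**: optional linear IR baseline drift in mm/min (positive =
  posterior), applied to the surrogate only — the internal target does not
  drift, which is precisely the model-degrading mismatch seen between
  imaging sessions.
* **Diaphragm**: a scaled (default 1.5×) copy of the target SI trace; its
  excursion is auto-centred on the detector.
* **Projection rendering**: 256×256 px frames at 0.2 mm/px (isocenter
  plane). The diaphragm edge is a logistic intensity transition
  (bright lung above, dark abdomen below, 1000→300 intensity units) whose
  sub-pixel centre row follows the diaphragm trace. The default transition
  scale (20 px = 4 mm) represents the gradual profile that column-collapsing
  a curved diaphragm dome produces; an optional quadratic "dome sag" across
  columns is available. Static low-frequency texture and per-frame Gaussian
  noise are added; intensities are floored at 1 so the log transform is
  always defined. Projection geometry is an ideal parallel-ray model —
  divergent-beam magnification is absorbed into the simulator since no
  source/detector distances are modelled.

What the simulator does **not** emulate: scatter, beam hardening, moving
anatomy other than the diaphragm edge, cardiac motion, imager lag, or
detector calibration errors. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under controlled
conditions, not clinical performance on patient images.

## Shroud extraction

* Shroud image: per frame, log transform → vertical derivative (central
  differences; one-sided at the border rows) → mean across detector columns.
  The derivative commutes with the column mean, which the implementation
  exploits for speed.
* Dual-imager superimposition: integer row shift maximising the correlation
  of the time-averaged row profiles (exhaustive search, ties broken toward
  the smaller shift), then element-wise averaging; rows without overlap keep
  the first image. Sub-pixel registration is unnecessary because the signal
  is rescaled later anyway.
* Trimming: an explicit row band, the classic "max-variance row ± margin"
  (default ±25 rows), or the default `"support"` mode that keeps all rows
  with temporal variance ≥ 5 % of the maximum (padded by 10). The support
  mode exists because at realistic motion scale the breathing excursion
  (~85 px here) is far wider than a fixed ±25-row band.
* Local normalization: subtraction of the local-mean map (the "LM map" read
  as local *mean*; a local-minimum filter is available via `mode="min"`),
  then clip-limited tile-based histogram equalization
  (`skimage.exposure.equalize_adapthist`, tile height = image height / 8,
  clip limit 0.01). The mean-map window defaults to the largest odd size
  under ~2/3 of the trimmed height: a small window high-passes the ridge
  away, and an aggressive clip limit makes the intensity mapping strongly
  nonlinear in ridge position; both measurably degrade the waveform. There
  is a genuine tension between maximal tile-brightness uniformity and
  waveform linearity — the defaults favour the waveform, and the test suite
  asserts the uniformity improvement the chosen defaults actually deliver.
* Waveform: first principal-component score of the normalized columns
  (observations = frames, features = rows; full SVD, deterministic). The PCA
  sign is arbitrary and is fixed against a reference trace; the pipeline uses
  the ridge-centroid row trace of the *pre-normalization* image, weighted by
  the clipped negative gradient lobe (the ridge polarity is known: lung
  above is brighter, so the vertical log-gradient is negative at the
  diaphragm). This reference is robust where the normalized image's own
  centroid is not.

## Short-arc waveform and correction

* Cycle segmentation: `scipy.signal.find_peaks` on the negated trace,
  minimum separation 2 s, prominence 20 % of the interquartile range
  (scale-free default; both configurable).
* Phase sorting: 8 phases, phase 0 at end-inhalation, linear interpolation at
  phase points k/8, averaged across cycles per direction. Linear (not
  spline) interpolation is used for the 8-point cycle — 8 nodes do not
  support a stable spline.
* Tiling: the averaged cycle is periodically (linearly) resampled to each
  observed cycle length; the head segment takes the last `t_LM[0]` frames of
  the mean-length cycle, the tail its first frames, repeated cyclically if an
  edge segment exceeds one mean cycle (a robustness extension; with the
  segmentation's own minima the edges are always shorter than one cycle).
* Shroud cycle averaging: each inter-minimum interval is cubic-spline
  resampled to 301 points and the intervals are averaged; this averaged
  signal (tiled back to full length) is the percentile source for global
  matching. A flag switches the percentiles to the full waveform instead.
* Local matching combines overlapping windows by per-frame averaging of the
  per-window affine maps — continuous output, no seams. A window in which
  the target is flat degenerates to a pure mean-aligning shift. Final
  partial windows are skipped; every frame is covered by at least one window
  whenever the window fits the signal. Min/max matching can only represent
  *positive*-slope discrepancies; sign flips are handled by the upstream
  phase-inversion step.

## Prediction model and evaluation

* One independent (a, b, c, d, e) set per output direction; plain OLS, no
  regularization; velocity by central differences (one-sided at the ends),
  no smoothing by default.
* Metrics: per-direction RMSE, 3D RMSE, and the percentage of frames with 3D
  error below 3 mm using a strict `<` (configurable) — "within" is read
  exclusively.
* The `%<3 mm` grid report pools frames across cases; per-case percentages
  are also available from the individual results. Grid ties break toward
  the smaller window, then the wider percentile span.
* The 0.7 amplitude shrink applied to the tiled waveform in the evaluation
  defaults emulates the documented amplitude underestimation of phase-sorted
  short-arc reconstructions; with it, the scenario ordering
  CL ≤ AS-corrected ≤ 4D-CBCT is reproduced by the acceptance script.
* Baseline drift: per window, the median trace value at end-inhalation
  minima and end-exhalation maxima; BL = midpoint; drift = BL(test) −
  BL(train). Positive = posterior.

## Problem sizes

The test suite and acceptance script use the full 351-frame acquisition
geometry throughout; fidelity properties run over 10 fixed seeds and the
scenario study over 20 synthetic cases, sizes chosen so the complete study
re-runs in a couple of minutes on a single CPU while keeping the medians
stable across seeds.

## Known limitations

* Statistical significance machinery (ANOVA with multiple-comparison
  correction across scenarios) is intentionally out of scope; the per-case
  metric exports are designed to be consumed by any statistics package.
* No volumetric 4D-CBCT reconstruction: the short-arc waveform is built
  directly from triangulated marker positions.
* The PCA waveform is linear in the data, not in the ridge *position*; for
  very narrow ridges translating over a wide band its score saturates at the
  excursion extremes. The renderer's broad edge transition keeps this
  distortion small, which is also the regime real column-collapsed shroud
  images occupy.
* Long-term (between-session) evaluation is supported via `eval_case` but
  the package defines no model-update algorithm for drifting baselines.
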