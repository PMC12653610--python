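# Methods

This note documents the models, parameter choices and numerical
conventions behind `rubbergrade`, and what the synthetic test bed does and
does not establish about real specimens.

## Colorimetry: the dual-path convention

Reference characterizations of the five commercial grades publish four
families of numbers per grade — mean 8-bit RGB, CIE 1931 XYZ, CIELAB and
a yellowness index — and these are mutually consistent only under a mixed
convention, which brute-force recomputation against the published table
confirms:

* The XYZ columns are the sRGB/D65 matrix applied **directly to the 8-bit
  RGB means**, with no transfer-function linearization and no rescaling
  ("raw-linear" path).  This reproduces all fifteen X/Y/Z entries to
  ±0.1.
* The L\*a\*b\* columns follow the standard colorimetric chain: normalize
  by 255, invert the IEC 61966-2-1 piecewise sRGB transfer function,
  apply the same matrix scaled so reference white has Y = 100, then the
  CIE 15:2004 equations with the D65 white point ("gamma-linearized"
  path).  This reproduces L\* to ±0.1 and b\* to ±0.2; a pure power law
  with γ = 2.2 is selectable but reproduces the printed values less
  closely (e.g. L\* 5.57 instead of 8.86 for the darkest grade).
* The yellowness indices match `YI = 100(cx·X − cz·Z)/Y` evaluated on the
  **raw-linear** XYZ with coefficients (1.28, 1.06) — not the ASTM E313
  D65 pair (1.2985, 1.1335), which yields e.g. 2.43 instead of 8.52 for
  white crepe on that path.  Both presets are exposed;
  `table_consistent` is the default grading preset.

Every `TristimulusXYZ` records its path and every serialized
`ColorVector` records path and preset, so downstream consumers can verify
which variant they received.  ΔE is CIE76 (plain Euclidean distance in
CIELAB); ΔE2000 and chromatic adaptation transforms are out of scope.

## Preprocessing

* **Flat-field gain.**  `I_corr = (I_raw − I_dark)/(I_white − I_dark)·ḡ`
  with ḡ the per-channel spatial mean of the *dark-subtracted* white
  reference over usable pixels.  Using the dark-subtracted mean (rather
  than the raw white mean) makes the correction unbiased: a specimen
  imaged under the same illumination field as the white tile recovers its
  true dark-free intensity.  Pixels with |white − dark| below 10⁻⁶ of
  full scale are masked and excluded from all downstream statistics —
  never propagated as NaN.  Correction is per channel; each of R, G, B is
  corrected with its own white/dark plane.
* **Denoising.**  Gaussian, σ = 1.2 px, nearest-neighbour boundaries
  (constant images are exact fixed points).
* **Focus gate.**  The underlying acquisition protocol gates on a
  "gradient-magnitude contrast metric > 0.7" without defining the metric.
  The stand-in implemented here is the 99.9th-percentile Sobel gradient
  magnitude of the corrected luminance divided by (4 × robust intensity
  range): an ideal one-pixel edge scores ≈ 1, and defocus lowers the
  score in proportion to the blur width (a σ = 4 px blur scores well
  below the 0.7 gate).  It is a stand-in, not a reconstruction of the
  original metric; the threshold is configurable.
* **Uniformity gate.**  CV of the white-reference luminance over the
  central 30 × 30 mm window (via the 0.5 mm/px pitch).  Measured
  centrally, mild radial vignetting yields ~2.6% on default synthetic
  scenes — under the 5% gate — while the same field measured over the
  full frame has 12.3% CV; both figures are consistent with a single
  vignetting field, which is why the gate is defined on the central
  window.
* **Exposure check.**  99th-percentile luminance of the corrected image
  against 60–80% of full scale; reported alongside the gates but not
  itself gating, since exposure is an acquisition-control property.
* **SNR.**  `20 log10(μ_white / σ_dark)` on luminance.  Zero dark noise
  reports an infinite-SNR sentinel with a warning flag.

## Segmentation

Otsu's threshold is an exhaustive scan of all cut points of the 256-bin
luminance histogram.  A bimodal histogram with an empty valley makes
every cut inside the valley *exactly* optimal; the midpoint of the
maximal plateau is returned (first-index tie-breaking is an accident of
floating-point summation order, as the property tests document).

Both polarity hypotheses (specimen darker or brighter than the stage) are
refined and validated; the hypothesis producing a valid ROI wins, ties
broken by area.

**Circularity** is `4πA/P²` with A the pixel count and P the length of
the marching-squares boundary contour smoothed by a 7-point circular
moving average.  The smoothing removes the staircase bias of digitized
smooth shapes: a digitized disc scores 1.00 (raw contour length would
give 0.90) while a sharp 25 mm square still scores ≈ 0.80–0.83, near the
analytic π/4 and below the 0.85 gate.  Note the geometric tension this
reveals: a *perfect square* specimen cannot pass a 0.85 circularity gate
under any consistent perimeter definition, so physical specimens passing
such a gate must have rounded corners; the gate threshold is
configurable.

**Area quantization.**  At 0.5 mm/px one pixel is 0.25 mm² and whole
boundary rows flip at once under sub-pixel shifts, so the 10 mm²-wide
area acceptance window [620, 630] is only a few quantization steps wide.
The synthetic generator therefore centers specimens on the pixel grid
(odd 121 × 121 px frames) and uses a 25 mm rounded square with 4.5 mm
corner radius, which digitizes to 623.25 mm² and circularity 0.92 —
comfortably inside both gates.  A 3 mm corner radius, by contrast,
digitizes to ~617 mm² and fails the area gate; no 25 mm rounded square
with corners ≲ 3 mm passes both gates simultaneously.

## Classification

The published decision tree lists splits YI < 9.5 (white crepe), YI < 31
(RSS5), a\* < −0.5 (STR5L vs STR5) and L\* > 20 (RSS3 vs extreme
outliers).  Taken literally in that order the tree cannot route RSS3 at
all: RSS3 has a\* = +4.85 (fails the a\* split toward STR5L) and a YI
range overlapping both STR grades.  The tree implemented here inserts the
lightness test *before* the a\* split — `20 < L* < 36.4` → RSS3, with
36.4 the midpoint of the RSS3 (26.5) and STR5 (46.3) mean lightness —
and keeps L\* > 20 as the published outlier guard.  This reordering is an
interpretation; it classifies all five published mean vectors correctly
and is the only ordering of the published splits that can.  All
comparisons are strict `<` as printed, and no input uses more than five.

Calibration computes per-grade mean ± 2 SD intervals for YI, L\*, a\*,
b\* from labeled training vectors (≥ 2 specimens per grade, sample SD).
Vectors outside *every* grade's intervals by more than a configurable
margin (default 2 additional SDs) return `unclassified` — an outcome
added deliberately so out-of-range inputs fail loudly instead of landing
in the residual STR5 leaf.

Given the published per-grade spreads, misclassification under Gaussian
sampling is structurally confined to adjacent decision boundaries: white
crepe ↔ RSS5 across YI = 9.5 (white-crepe YI tail, z ≈ 1.9), RSS5 → STR
leaves across YI = 31 (z ≈ 1.2), STR5 ↔ STR5L across a\* = −0.5, and the
low-lightness RSS3 tail across L\* = 36.4 (z ≈ 2.4).  RSS3 ↔ white crepe
confusion is impossible by more than five SDs.  The property tests assert
exactly this structure.

## Synthetic scenes

`make_scene` emulates one acquisition: a centered rounded-square specimen
at the grade's mean RGB (optionally drawn with the grade's
specimen-to-specimen SD) on a mid-gray stage (level 170), multiplied by a
radial-quadratic vignetting field with spatial CV 12.3% over the frame,
plus dark current (level 8), additive Gaussian sensor noise (SD 2 counts
per frame, three frames), and a white-reference tile (level 190) sharing
the same field.  The field shape is `1 + β(ū − u)` with `u = (r/r_max)²`
— radial-quadratic, center bright — scaled exactly to the target CV; only
the CV is specified by the acquisition protocol, the shape is a modeling
choice.  Frames are quantized to integer counts, so identical seeds give
bit-identical scenes.

Stage and white levels were chosen once so that (a) all five grade means
are well separated from the background for both Otsu polarities, (b) the
vignetted frames stay below saturation (max ≈ 240 counts), and (c) the
corrected image's 99th-percentile luminance falls in the 60–80% exposure
band.  With these defaults the white-reference SNR is ≈ 42 dB and
segmentation succeeds on ≥ 99% of 200 seeded scenes spanning all grades.

What the generator does **not** emulate: surface texture and smoke
mottling, specular highlights, contamination (dust, residual chemicals),
specimen aging, irregular cut geometry, or chromatic illumination drift.
Tests passing on synthetic scenes therefore establish the correctness of
the measurement and decision chain under the stated statistical model of
the rig — not robustness to production-floor specimen variability.

## Statistics

* ANOVA is the classical fixed-effects decomposition; the zero
  within-variance edge cases report F = 0, p = 1 (identical groups) or
  F = ∞, p = 0 (separated constant groups) instead of dividing by zero.
* Tukey HSD delegates to the studentized-range implementation in SciPy;
  for two groups its decision coincides with the two-sample t-test.
* Repeatability/reproducibility follow the ISO 5725-2 one-factor
  decomposition: s_r² is pooled within-session variance, s_L² =
  max(0, (MS_between − MS_within)/n̄), s_R² = s_r² + s_L²; a single
  session flags reproducibility as undefined.
* Uncertainty propagation is Monte-Carlo (default 10⁵ draws, seeded):
  RGB ~ N(mean, sd) clipped to [0, 255], pushed through the
  table-consistent YI path.  Monte-Carlo was chosen over an analytic
  delta method because it is assumption-light and self-verifying (the
  tests check seed stability, local linearity in the input SD, and < 2%
  drift on doubling the sample size).  Published between-method F
  statistics for the measurement-equivalence comparison are not
  recomputable from their own summary rows, so method equivalence is
  validated qualitatively — a seeded null simulation at the white-crepe
  parameters is non-significant in ≥ 90% of replicates — rather than
  numerically.
* Shapiro–Wilk and Levene assumption checks delegate to SciPy.

## Problem sizes

Deterministic reproduction targets run on the five published mean RGB
triples.  Stochastic checks use: 200 seeded scenes (40 per grade) for the
segmentation success rate, 20 draws per grade for confusion structure,
100 replicates for the ANOVA null simulation, 10⁵ Monte-Carlo draws for
uncertainty propagation, and a 200 × 200 px scene for the flat-field
residual CV.  The full suite runs in a few seconds on one CPU.

## Known limitations

* The table-consistent YI coefficients (1.28, 1.06) are reverse-derived
  from the published table; the discrepancy with the ASTM E313
  coefficients printed alongside it is documented but cannot be resolved
  from the available material.
* The decision-tree reordering (lightness before a\*) is an
  interpretation of an ambiguous published rule order.
* The focus metric is a stand-in for an undefined acquisition metric.
* Grading thresholds are fixed numbers calibrated for these five grades;
  intermediate or novel grades return `unclassified` at best.
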