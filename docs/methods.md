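# Methods

## Threshold-based fat quantification

The measurement assumes that on T1-weighted fast-spin-echo images fat is
reliably hyperintense relative to muscle, so that the intensity histogram
of a muscle ROI containing fat is bimodal. Otsu's criterion picks the cut
t\* maximizing the between-class variance σ²_B(t) = ω₀ω₁(μ₀ − μ₁)² over
candidate cuts; pixels strictly above t\* are counted as fat. Choices that
needed fixing where the underlying idea is silent:

- **Histogram domain.** The histogram is built over the ROI's own min–max
  intensity span with `n_bins = 256` (not the DICOM bit depth, not the
  whole image). A per-ROI, per-slice threshold adapts to local contrast
  and makes muscle and fossa measurements independent; 256 bins matches
  the classic 8-bit formulation of the criterion. It is equally defensible
  to histogram the whole image or share one threshold between regions;
  the per-ROI variant is the one implemented and tested.
- **Candidate cuts and class statistics.** Cuts are interior bin edges;
  class probabilities and means are computed from bin centers. Ties in
  σ²_B are broken toward the lowest threshold (determinism; on truly
  bimodal data ties occur only across the empty inter-class gap, where
  every cut yields the same pixel partition).
- **Degenerate ROIs.** A constant-intensity ROI has no contrast and hence
  no detectable fat: the fraction is reported as 0 with a degenerate flag
  and a logged warning rather than an error or NaN. ROIs below
  `min_roi_pixels = 25` are rejected — a histogram of fewer pixels does
  not support a meaningful two-class split.
- **Endpoints.** Per-slice fractions on three consecutive slices (the
  spectroscopy slice and its two neighbours) are combined by an
  unweighted arithmetic mean. The occupation ratio is the raw pixel-count
  ratio muscle/fossa; values above 1 or a muscle not contained in the
  fossa produce warnings, not errors, since observer contours can
  legitimately disagree at the boundary.
- **Sensitivity model.** The effect of a relative segmented-area error δ
  on a true fat proportion F is propagated to first order, ΔF = 100·F·δ
  percentage points, interpreting the added/removed rim as non-fat
  pixels. The exact dilution model F/(1+δ) differs only at second order
  for single-digit-percent δ and is noted in the code.

Intensities are converted to physical units (rescale slope/intercept) at
load time so thresholds are comparable across slices. Polygon ROIs are
rasterized with a boundary-inclusive pixel-center rule in (x=col, y=row)
continuous coordinates; the rule is exact and deterministic.

## MRS peak fitting

The magnitude spectrum is modelled as a constant baseline plus two
Gaussians, water near 4.7 ppm and methylene lipid near 1.3 ppm, each
searched within ±0.5 ppm of its nominal position. Initialization takes
the window maxima above a robust noise floor (median ± 1.4826·MAD of the
spectrum away from both windows); a peak that does not rise 3 noise SDs
above the floor raises a missing-peak error naming the peak. The
Levenberg–Marquardt/trust-region fit is budgeted at 500 iterations of the
7-parameter model and reports the residual RMS. The fat/water ratio is
the ratio of fitted **amplitudes**; the Gaussian **area** ratio
(A·σ_lipid)/(A·σ_water) is available behind a flag, since vendor
summaries are ambiguous about which "magnitude" they report. A constant
baseline is the minimal testable choice for short-TE magnitude spectra;
spectra are stored with an ascending ppm axis (descending input is
flipped on load). Not modelled: J-coupling multiplets, frequency/phase
drift, water saturation, vendor raw formats.

## Goutallier consensus

Grades 0–4 from ≥2 raters are averaged and rounded to the nearest
integer. Rounding is half-up: with three raters the mean is a multiple of
1/3 and the .5 tie can never occur (asserted in tests), but even rater
counts can produce it and need a stated rule. No tie-breaker re-read is
modelled.

## Validation statistics

- **ICC.** Two-way random-effects, absolute-agreement, single-measurement
  ICC(2,1) from the mean-squares decomposition — the conservative
  convention for multi-reader radiology reliability — with the
  Shrout–Fleiss F-based confidence interval (Satterthwaite df for the
  MSC/MSE mixture). The k-rater average form ICC(2,k) is available via a
  flag. Cross-checked in tests against an independent implementation and
  a longhand decomposition.
- **CV.** Per-subject 100·sd/mean across observers with the sample (n−1)
  SD; requires strictly positive measurements.
- **ANOVA / Tukey.** One-way fixed-effects ANOVA from the sums-of-squares
  decomposition. The boundary case of zero within-group variance with
  unequal means reports F = ∞ and p at the smallest positive float
  rather than NaN. Post hoc comparisons use Tukey–Kramer standard errors
  (the grade groups are unbalanced) with p from the studentized range
  distribution with (k, N−k); verified against a 100 000-draw Monte-Carlo
  sampling of the null max-range law on equal-n groups, where the Tukey
  p is exact.
- **Pearson.** Product-moment R with p via the t transform.
- **Post-hoc power from summaries.** When only group means, 95% CIs and
  sizes are published, group SDs are recovered by inverting the t-based
  CI (halfwidth·√n / t_{0.975,n−1}), pooled into a within-group variance,
  and the noncentrality λ = Σ n_g(mean_g − grand)²/σ²_pooled feeds the
  noncentral-F power at α = 0.05 two-sided. Correlation power uses the
  Fisher-z normal approximation, power = Φ(√(n−3)·atanh r − z_{0.975}) +
  Φ(−√(n−3)·atanh r − z_{0.975}). Both are verified against Monte-Carlo
  simulation to ±0.02.

The published 38-subject reference summaries that feed the power
reconstructions live in `suprafat.reference`. The headline reliability
and correlation values reported for that cohort (ICCs near 0.98, R² of
0.83) were computed on per-patient data that were never released; they
are recorded as context and are not recomputable here.

## Synthetic data: what it emulates, and what it does not

The phantom is a rounded-triangle "fossa" (a dilated shrunk triangle)
containing a concentric "muscle" defined as the deepest
`round(occupation·n_fossa)` pixels by distance transform — so occupation
ratios are exact by construction. Fat is planted as random-orientation
streak segments (width 3 px, length 0.3–0.8 of the muscle diameter)
until exactly `round(f·n_muscle)` pixels are fat; the extramuscular fossa
is filled at fat intensity, emulating atrophy. Intensities default to
μ_muscle = 100, μ_fat = 180, Gaussian noise σ = 10 — a class separation
of 8σ, reflecting the high fat/muscle contrast of T1 imaging — with a
Rician option for magnitude-image realism. Truth records carry exact
integer pixel counts, so recovery tests are sharp. All randomness flows
through a single seeded generator.

Observer variability is emulated by growing/shrinking a mask boundary in
distance order (random tie-breaks) to an exact relative area change δ,
drawn from ±(2–5)% per observer — matching reported inter-observer area
variation of a few percent while preserving connectedness.

The linked cohort draws each subject's true muscle fat proportion f from
a per-grade band following the visual grade definitions — (1.5–3)%,
(3–10)%, (10–35)%, (35–50)%, (50–80)% for grades 0–4 — with the grade mix
(8, 16, 45, 13, 18)% apportioned by largest remainder (38 subjects give
groups of 3/6/17/5/7). The true MRS ratio is linked linearly,
ratio = 2.0·f + ε with ε ~ N(0, 0.03²); the slope is consistent with the
reference cohort's ratio-to-fraction quotient (≈1.8–2) and a linear link
makes the noiseless pipeline correlation exactly 1. Spectra are generated
at water SNR 200 (σ = 0.005 for unit water amplitude), realistic for a
1 cm³ voxel at 32 averages and high enough that grade-0 lipid peaks
(ratio ≈ 0.03) clear the 3σ detection floor.

What the phantoms do **not** emulate — and hence what passing tests do
not demonstrate about clinical data: scanner bias fields and coil
shading, partial-volume voxels at fat/muscle boundaries, arthrographic
contrast leakage, anatomically realistic scapular geometry, correlated
inter-observer disagreement (human observers err systematically, not by
uniform boundary offsets), and lipid multiplet structure in spectra.
Recovery at 8σ separation bounds the best case; real T1 contrast varies.

Grade bands start at 1.5% rather than 0 deliberately: Otsu has no
meaningful threshold on an effectively unimodal histogram. Below roughly
1% fat at 8σ separation the pure-noise split overtakes the inter-class
cut and the estimate jumps to tens of percent. Clinically even "no fat"
muscle shows a small fat-bright pixel fraction (perimysial fascia,
chemical-shift artifact), so the floor is realistic — but it is a genuine
limitation of the method that near-zero fat fractions are not
measurable by simple clustering thresholds, and the recovery guarantees
tested here (|error| ≤ 2 percentage points at separation ≥ 6σ) hold for
f ∈ [0.05, 0.6].

## Problem sizes

Default phantoms are 96×96 px (≈2 500-pixel muscles); cohorts are 38
subjects × 3 slices with 4 observers; recovery suites use 50 phantoms and
200 spectra; Monte-Carlo oracles use 20 000–100 000 draws. These sizes
give sampling error comfortably below the asserted tolerances while the
whole suite runs in well under a minute on one core.
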