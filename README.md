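# suprafat

Threshold-based quantification of fatty degeneration in the supraspinatus
muscle on standard T1-weighted shoulder MRI, together with the apparatus
used to validate it: single-voxel MR-spectroscopy peak fitting, Goutallier
consensus grading, and inter-observer reliability / group-comparison
statistics. Everything is testable end to end on seeded synthetic phantoms
with exact pixel-level ground truth — no patient data required.

## Who this is for

Musculoskeletal imaging researchers who want a reproducible, observer-
independent fat-fraction measurement from ordinary T1-weighted images —
without quantitative sequences such as Dixon or spectroscopic imaging —
and a statistics toolbox to validate it against visual Goutallier grades
and single-voxel MRS.

## The method

Fat is hyperintense on T1. Given a manually segmented region of interest
(the supraspinatus muscle, or the whole supraspinatus fossa), the ROI's
intensity histogram is split by **Otsu's threshold**: the cut *t\** that
maximizes the between-class variance

σ²_B(t) = ω₀(t)·ω₁(t)·(μ₀(t) − μ₁(t))²,

where ω₀, ω₁ are the probabilities and μ₀, μ₁ the means of the dark
(muscle) and bright (fat) intensity classes. The **fat fraction** is the
percentage of ROI pixels above the threshold,

F = 100 · N_fg / (N_fg + N_bg),

computed per slice with an ROI-local threshold and averaged over three
consecutive sagittal slices centred on the MRS voxel slice. Companion
endpoints: the **occupation ratio** (muscle area / fossa area, an atrophy
index) and the first-order **segmentation-error sensitivity**
ΔF = 100·F·δ for a relative area variation δ.

The reference standard is the **MRS fat/water ratio**: a least-squares fit
of two Gaussians plus a constant baseline to the magnitude spectrum, with
the water peak near 4.7 ppm and the lipid peak near 1.3 ppm; the ratio of
fitted amplitudes A_lipid/A_water is the reference fat measure. Validation
statistics include ICC(2,1) with F-based confidence intervals, per-subject
coefficients of variation, one-way ANOVA with Tukey–Kramer post hoc
comparisons, Pearson correlation, and post-hoc power reconstructed from
published group summaries (means, 95% CIs, group sizes).

## Worked example

```python
from suprafat import (PhantomSpec, generate_phantom, slice_fat_fraction,
                      occupation_ratio, generate_spectrum, fit_peaks,
                      area_error_sensitivity)

spec = PhantomSpec(true_fat_fraction=0.40, seed=7)   # 40% fatty streaks
image, muscle, fossa, truth = generate_phantom(spec)
frac, result, (n_fg, n_bg) = slice_fat_fraction(image, muscle)
print(f"true muscle fat fraction : {truth.muscle_fat_fraction:.2f}%")
print(f"estimated fat fraction   : {frac:.2f}%")
print(f"occupation ratio         : {occupation_ratio(muscle, fossa):.3f}")

fit = fit_peaks(generate_spectrum(0.30, noise_sigma=0.02, seed=1))
print(f"MRS fat/water ratio      : {fit.fat_water_ratio:.3f}")
print(f"sensitivity at F=0.80, delta=0.04: "
      f"{area_error_sensitivity(0.80, 0.04):.1f} percentage points")
```

prints

```
true muscle fat fraction : 39.98%
estimated fat fraction   : 39.98%  (threshold 132.4, 996 fat / 1495 muscle pixels)
occupation ratio         : 0.600
MRS fat/water ratio      : 0.303  (water 0.996 @ 4.70 ppm, lipid 0.302 @ 1.30 ppm)
sensitivity at F=0.80, delta=0.04: 3.2 percentage points
```

The phantom plants exactly `round(0.40 × 2491) = 996` fat-intensity streak
pixels in a 2491-pixel muscle; at the default 8σ class separation the
ROI-local Otsu threshold (132.4, in the gap between the muscle mode at 100
and the fat mode at 180) recovers the planted fraction exactly. The MRS
fit recovers the simulated ratio 0.30 to within the noise. The last line
is the lower edge of the 3.2–7.2 point sensitivity band for an 80%-fat
muscle under the 4–9% inter-observer area variation.

The same workflow is available from the shell:

```bash
suprafat simulate phantom --out demo --seed 42
suprafat quantify --slices demo/slice.dcm ... --muscle demo/muscle.png ... \
                  --fossa demo/fossa.png ... --out demo/result.csv
suprafat mrs-fit --spectrum spectrum.csv
suprafat consensus --ratings ratings.csv
suprafat stats icc --input matrix.csv
suprafat sensitivity --fat-fraction 0.8 --delta 0.04
```

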