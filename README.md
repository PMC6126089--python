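# sarcospace

Measurement of striation spacing — sarcomere length (SL) or T-tubular
distance — from fluorescence microscopy images of cardiac myocytes.

## The problem

In striated muscle imaged with a Z-disk label (e.g. α-actinin–GFP) or a
membrane stain marking T-tubules, the contractile structure appears as a
train of bright bands along the myocyte's long axis, spaced roughly
1.2–2.4 μm depending on contractile state. The band spacing *is* the
physiological readout: relaxed ventricular sarcomeres sit near
1.9–2.2 μm, contracted ones well below. Measuring it precisely from
noisy confocal frames is the task this package automates, for
microscopists and muscle physiologists who currently do it by hand in
ImageJ.

## The method

1. **Profile** — the fluorescence intensity is sampled along a straight
   line ROI drawn down the myocyte axis (1-pixel steps, averaged over an
   odd ROI width, default 5 px, by bilinear interpolation).
2. **Fit** — the profile is fitted with a multipeak Gaussian model on a
   linear offset by Levenberg–Marquardt least squares:

   *Y*(*X*) = *aX* + *b* + Σᵢ *A*ᵢ exp(−(*X* − μᵢ)² / 2σᵢ²)

3. **Filter** — peaks with insufficient fluorescence intensity
   (amplitude below 20 % of the median fitted amplitude, configurable)
   are excluded; distances adjacent to an excluded peak are dropped,
   never bridged.
4. **Spacing** — SL or T-tubular distance is the distance between the
   centers μᵢ of adjacent kept peaks, reported as mean ± sample SD.
5. **Superposition** — repeated frames of an arrested heart can be
   averaged pixelwise first (noise SD falls as 1/√n), which is what
   makes dim membrane stains fittable.
6. **Tilt correction** — a myocyte tilted out of the image plane by θ
   shows its bands stretched by 1/cos θ; with optical section thickness
   *t* and in-focus length *L*min, θ = arcsin(*t*/*L*min). The factor is
   reported (≈1.02 for *L*min = 70 μm), not silently applied.
7. **Statistics** — Welch's t-test (raw data or printed mean ± SD, n
   summaries) for two groups; the Steel–Dwass all-pairs rank test for
   three or more.

A synthetic striated-image generator with exact ground truth
(`sarcospace.synthetic`) stands in for microscope data, so the whole
pipeline is testable end to end.

## Worked example

```python
from sarcospace import (StriationScene, analyze, axis_roi,
                        generate_striation_image)

scene = StriationScene(true_spacing=1.92, n_bands=10, seed=1).with_snr(10)
image, truth = generate_striation_image(scene)
result = analyze(image, axis_roi(scene))
print(f"spacing {result.spacing.mean:.2f} ± {result.spacing.sd:.2f} um "
      f"(n={result.spacing.n})")
```

prints

```
spacing 1.92 ± 0.02 um (n=9)
```

Ten bands laid down at 1.92 μm with band signal-to-noise ≈ 10 give nine
adjacent-peak distances whose mean recovers the truth to a few
nanometres; the SD here reflects fit noise, not biology. The same flow
runs from the shell:

```bash
sarcospace simulate --spacing 1.92 --snr 10 --seed 1 --out sim/
sarcospace analyze --image sim/image.tif --roi sim/roi.json --out report/
sarcospace compare --method steel_dwass a.csv b.csv c.csv
```

Group comparisons from printed summaries work without raw data:

```python
from sarcospace import SummaryStats, welch_t
r = welch_t(SummaryStats(2.18, 0.13, 9), SummaryStats(1.80, 0.08, 9))
print(f"t={r.statistic:.2f}, df={r.df:.1f}, p={r.p_value:.1e}")
# t=7.47, df=13.3, p=4.1e-06
```

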