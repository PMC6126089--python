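# Methods

## Measurement model

A striated myocyte labeled at its Z-disks (or T-tubules) is treated as a
1-D periodic band train along its long axis. After PSF blur each band's
cross-section is approximately Gaussian, so the intensity profile along
a line ROI is modeled as

    Y(X) = a·X + b + Σ_i A_i · exp(−(X − μ_i)² / (2σ_i²))

with a linear offset absorbing background and slow shading gradients.
All parameters are fitted jointly by Levenberg–Marquardt damped least
squares (MINPACK via lmfit, with box bounds handled by parameter
transformation). Joint fitting is the stricter reading of "Gaussian
peaks on a linear offset": baseline and peaks compete for the same
intensity, so fitting them sequentially can bias amplitudes where bands
sit on a steep gradient.

The spacing statistic is the distance between centers of adjacent
peaks; the report is mean ± sample (n−1) SD over kept distances. The
(n−1) divisor is the convention for small-n mean ± SD reporting.

### Initialization (deterministic)

* Baseline guess: least-squares line through the samples at or below
  the profile median — the bands occupy the upper half of the intensity
  distribution, so the lower envelope tracks the offset.
* Peak candidates: local maxima of the Gaussian-smoothed
  (σ = 0.15 μm), baseline-subtracted profile with prominence ≥ 10 % of
  the signal maximum and mutual separation ≥ `min_separation`
  (default 0.8 μm, comfortably below the shortest physiological
  spacing ~1.2 μm). A profile whose baseline-subtracted signal is
  numerically flat has no striations regardless of relative prominence.
* Initial σ = `min_separation`/4; initial amplitude = the residual at
  the candidate.

Fewer than two candidates is an "insufficient striations" error. When
the caller forces a peak count above the number of candidates, extras
are seeded beside the strongest candidates; if the data do not support
them they collapse (centers closer than `min_separation`/2) or vanish
(amplitude → 0), both flagged in `MultiPeakFit.collapsed`.

### Fit parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `sigma_bounds` | (0.1, 1.0) | μm | below the PSF no band can be narrower; above 1 μm "bands" are merging |
| `min_separation` | 0.8 | μm | below the physiological spacing range |
| `min_prominence_frac` | 0.1 | — | rejects noise ripples while keeping dim real bands |
| `min_amplitude_frac` | 0.2 | — | insufficient-fluorescence filter (below) |
| `tolerance` | 1e-8 | rel. | RSS/parameter change convergence criterion |
| `max_iterations` | 200 | — | per-parameter function-evaluation budget |

Each peak carries an independent σ: striation widths genuinely vary
along a myocyte, and a shared width would bias centers near dim or
broadened bands.

### Insufficient-fluorescence filter

Bands too dim to constrain a center are excluded after fitting:
amplitude < 20 % of the median fitted amplitude (the threshold is a
package choice — the practice of excluding dim striations is standard,
but no quantitative rule is established; the value is configurable and
recorded in every report). Distances adjacent to an excluded peak are
flagged and dropped from the statistics. They are never replaced by the
center-to-center distance across the gap: that bridged distance is ~2
periods and would corrupt the mean.

### Profile extraction

Samples at 1-pixel steps along the ROI (the de-facto line-profile
convention), bilinear interpolation for off-grid points, mean over the
odd ROI width (default 5 px). Averaging rather than summing across the
width only rescales amplitudes, never peak positions. Coordinates are
continuous, origin at the center of the top-left pixel. A ROI whose
averaging band leaves the image is an error — no silent clamping.

### Superposition

Pixelwise mean over frames; with n frames noise SD falls by √n.
Registration (integer-pixel translation maximizing cross-correlation
with frame 0, overlap-only averaging at borders) is opt-in and off by
default: frames of an arrested heart are nominally aligned, and
registering pure noise can lock onto spurious correlations.

### Tilt-projection correction

Parallel striation planes tilted out of the image plane by θ project at
spacing true/cos θ. θ is not observable directly, but an optical
section of thickness t crossing a myocyte that stays in focus over
length L_min in the image plane implies sin θ = t/L_min, giving the
overestimation factor 1/cos(arcsin(t/L_min)) — this geometric reading
is the package's own derivation. The default t = 13.8 μm is
back-derived so that L_min = 70 μm corresponds to a 2 % factor,
matching the rule of thumb that myocytes in focus over ≥ 70 μm carry
negligible (≲2 %) tilt error. The factor is *reported*, not applied;
`corrected_spacing` divides it out on request.

## Statistics

* **Welch's t-test**: t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂),
  Welch–Satterthwaite df, two-sided p. Accepts raw distances or printed
  (mean, SD, n) summaries; raw input is summarized first so both routes
  agree exactly. Note: one published figure-legend pair
  (2.24 ± 0.05 vs 2.10 ± 0.23, n = 9 each) evaluates to p ≈ 0.11 under
  this formula while the legend prints p = 0.15; the legend's exact n
  or pairing is not recoverable, so the formula is implemented as
  stated and the discrepancy simply noted.
* **Steel–Dwass** all-pairs comparison: each pair jointly ranked
  (average ranks for ties), rank sum standardized with the
  tie-corrected variance, q = |z|·√2 referred to the studentized-range
  distribution with k groups and infinite df (the standard asymptotic
  null). For k = 2 this reduces exactly to the two-sided
  normal-approximation Wilcoxon test. An exhaustive-permutation mode
  (n ≤ 8 per group) exists for validation; the asymptotic p can differ
  from the exact permutation p by >0.1 at n = 4 per group, which is a
  property of the normal approximation, not a defect of either mode.
  Two-sided tests throughout.

## Synthetic data

The generator renders the measurement model itself: Gaussian bands
spaced `true_spacing/cos(tilt)` along an axis at arbitrary in-plane
angle, linear background, per-band amplitudes drawn uniform in
[0.5, 1.0]·amp_max (mimicking the band-to-band variation of membrane
stains; an explicit list can plant dim bands for filter tests), and
i.i.d. additive Gaussian noise — an EMCCD readout-dominated
approximation. Band SNR is defined as expected band amplitude over
noise SD (0.75·amp_max/noise_sd). Defaults: 0.27 μm/px (a 512-px field
≈ 138 μm, consistent with a 60× objective), 10 bands, band σ 0.3 μm,
image 64×128 px. Everything is deterministic given the scene seed;
frame stacks draw noise sequentially from the scene-seeded generator so
a 1-frame stack is bit-identical to the single-image path.

What the generator does **not** emulate: Poisson photon statistics,
the true (non-Gaussian, anisotropic) PSF, capillaries and neighboring
cells, curved myocytes, motion, or focus drift. Passing recovery tests
therefore demonstrate correctness of the estimator under the model's
assumptions — matched model class, straight axis, stationary noise —
not robustness to every real-world artifact. The study conditions used
in tests: spacings {1.3, 1.9, 2.0, 2.15, 2.25} μm spanning contracted
to stretched sarcomeres, SNR ≈ 10 for single clean frames, SNR ≈ 2 with
25 frames for the superposition contrast (a dim membrane stain at short
exposure).

## Numerical choices and degenerate inputs

* LM convergence: relative tolerance 1e-8, evaluation budget
  200·(2+3k); non-convergence returns `converged=False` rather than
  raising — the caller decides.
* Exactly tied fitted centers are nudged apart by one ulp to preserve
  the strict ordering invariant.
* Constant image + automatic (Otsu) threshold in `labeled_fraction` is
  an error (no bimodality), as is a stack-registration result leaving
  pixels uncovered.
* Zero-variance Welch comparisons: equal means raise a degenerate-input
  error; unequal means give t = ±∞, p = 0.
* The spacing SD is NaN when only one kept distance remains (sample SD
  undefined at n = 1).

## Problem sizes

Monte-Carlo suites run at desk scale: 50 seeds per spacing for
recovery, 20 seeds × 25 frames for superposition, 1000 replicates for
the Steel–Dwass type-I calibration — sizes at which the binomial
uncertainty on each rate is comfortably smaller than the margin to its
pass bound.

## Known limitations

* No automatic myocyte-axis detection: ROIs are user-drawn (or derived
  from the synthetic scene), matching actual practice.
* No Fourier/autocorrelation spacing estimator; fitting is the method
  implemented, and spectral estimators would not localize individual
  dim bands.
* Registration is integer-pixel only; sub-pixel drift blurs rather
  than shifts.
* The tilt correction assumes a straight axis crossing the section
  once; curved or branching myocytes violate it.
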