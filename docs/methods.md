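# Methods

This note documents the models, numerical choices and limitations behind
`ctdenoise`, in the spirit of the methods documentation of packages such as
statsmodels or scanpy.

## The digital phantom

The simulated object is a single axial slice through a 3D-printed
anthropomorphic head phantom: a 16 cm cylinder of water-like plastic
(background attenuation 0.190 cm⁻¹ by default — the true attenuation of the
printed PLA case is not known, so a water-like value is used and is
configurable) holding five 2.5 cm cylindrical inserts. Insert intensities
equal the measured linear attenuation coefficients of the filament
materials, in cm⁻¹: XT-CF20 0.208 (mimicking CSF), wood 0.213 (gray
matter), air 0.0, ABS 0.214 (white matter), bronze 0.839 (bone). Since all
values lie below 1 cm⁻¹, pixel intensities are numerically equal to μ on
the nominal [0, 1] display scale.

Geometry defaults: 512×512 pixels at 0.5 mm spacing (25.6 cm field of view;
the spacing is configurable and all frequency-domain quantities inherit
it). Insert placement — one insert at the center and four on a 50 mm ring
at 90° spacing — is a package choice; the physical phantom's exact hole
coordinates are not part of the model. Rasterization assigns a pixel to a
circle iff its center lies inside (no anti-aliasing), so every ROI in the
clean image is exactly piecewise constant.

Noise: zero-mean i.i.d. Gaussian with "intensity" interpreted as the
**variance** on the [0, 1] image (the MATLAB `imnoise` convention), with the
result clamped to [0, 1]; both the variance-vs-standard-deviation reading
and the clamping are switchable (`NoiseSpec(mode="std", clip=False)`). The
study intensities are 0.001, 0.005, 0.01, 0.05, 0.1.

The generator emulates the *image-domain* noise situation only: no
projection physics, no reconstruction kernel correlations, no beam
hardening, no metal artifacts (the bronze insert is rendered but not
evaluated, mirroring the physical study where its signal saturated the
scale). Passing tests on this phantom therefore demonstrates algorithmic
correctness and the qualitative noise-level trends, not performance on
scanner data with correlated noise texture.

## Non-local means and its fast form

For pixel m, candidates n range over a square search window of half-width
`search_radius` (default 5, an 11×11 window). The patch distance is a
Gaussian-weighted **mean** squared difference over patch offsets τ of
half-width `patch_radius` (default 2, 5×5 patches):

    D(m,n) = Σ_τ G_σ(τ) (I(m+τ) − I(n+τ))²,   Σ_τ G_σ(τ) = 1,

with σ = `patch_radius`/2 by default and a uniform-patch option (σ → ∞).
Normalizing G keeps the useful range of the smoothing factor d comparable
across patch sizes and — on this phantom — places the half-slope points of
all five study noise levels inside the standard d ∈ [0.01, 1.00] sweep.
Weights are ω = exp(−D/d²)/Z; the center pixel receives the maximum of its
neighbours' weights (standard practice; the literal exp(0) = 1 is available
via `self_weight="one"`). Boundaries use symmetric (mirror) padding, so
constant images are exact fixed points.

The fast path computes, per offset τ, the shifted squared-difference image
once and integrates it over the patch support with one-dimensional
cumulative-sum tables (uniform patch) or separable 1-D Gaussian passes, so
cost per pixel is independent of patch size. Numerical stabilization:
because weights are normalized per pixel, all of them can be rescaled by
exp(D_min/d²) without changing the output; this is applied before
exponentiation so that tiny d never underflows the denominator. The
brute-force per-pixel implementation is retained as the oracle; the two
agree to ~1e−15 and the test suite enforces < 1e−10.

Because NLM output at a pixel depends only on pixels within
`patch_radius + search_radius`, the parameter sweep denoises only ROI-sized
crops padded by that margin — bit-identical to full-image denoising
(verified by test) at a fraction of the cost — and the per-offset distance
tables, which do not depend on d, are computed once per image and reused
across the whole d grid.

## Comparator filters

* Gaussian: normalized Gaussian convolution, σ = 1 px default.
* Adaptive Wiener: out = μ + max(σ²−σ²_n, 0)/max(σ², σ²_n)·(in−μ) with
  local moments over a 5×5 window; σ²_n estimated as the mean local
  variance when not supplied. Implemented on `scipy.ndimage` primitives so
  that boundaries use symmetric padding (the stock `scipy.signal.wiener`
  zero-pads, which breaks the constant-image fixed-point property).
* Total variation: Rudin–Osher–Fatemi minimization ‖u−f‖²/2 + w·TV(u) via
  Chambolle's dual projection (scikit-image backend), w = 0.1·√v matched to
  the noise intensity v by default, 200 iterations, tolerance 1e−5.

Comparator parameters are package defaults (the original study does not
report its filter settings); all are configurable and echoed into output
provenance.

## Image-quality metrics

Conventions (fixed once, tested): ROIs are 0-based half-open rectangles;
standard deviations are population (divisor n); CNR keeps its sign; COV is
σ/μ. The default layout places one 15×15 px ROI at each tissue insert
center, a paired background ROI in case bulk on the insert ring rotated by
45° (half-radius position for the central insert), four 64×64 px NNPS ROIs
in the scan-air corners, and one visual ROI straddling the central insert's
boundary. A layout is rejected if any metric ROI crosses a material
boundary of the clean phantom.

NNPS: the air region is tiled (64×64 tiles, half-overlap), each tile is
detrended by its mean (a planar-ramp option exists), and
|DFT|²·Δx·Δy/(N_x·N_y) is averaged over all tiles and noise realizations,
then divided by the squared large-area mean signal and radially binned
(bins Nyquist/64 wide, DC excluded, frequencies above Nyquist dropped).
Because synthetic scan air is exactly zero-valued, dividing by its squared
mean would explode; when the air mean is below 0.01 the pipeline normalizes
by the phantom-bulk mean instead and records that choice in the provenance.
Two closed forms anchor the implementation: the NPS frequency integral
equals the mean detrended tile variance (Parseval), and white noise of
variance v gives a flat NNPS of level v·Δ²/μ².

## Half-slope optimization

CNR(d) and COV(d) on this phantom rise (respectively fall) steeply and then
saturate. The selection rule returns the smallest d at which the slope
magnitude has fallen to half its maximum *and stays there*. Numerically the
slope is estimated with a centered quadratic Savitzky–Golay derivative
(window 13 grid points by default; window 1 falls back to plain central
differences), and a decreasing isotonic regression is fitted to the slope
magnitude from its peak onward — the theoretical slope magnitude of a
saturating curve is monotone beyond its peak, so the isotonic fit denoises
the estimate and makes the persistence condition exact. The half-reference
crossing is located by linear interpolation on the fit and snapped to the
nearest grid point. The reference slope is the maximum *observable* slope:
for y = 1 − exp(−d/L) sampled from d₀ = 0.01 the recovered point is
d₀ + L·ln 2, and a discontinuous slope break is localized to within about
half the derivative window (verified at ±2 grid steps for the default
window). On 200 synthetic saturating curves with additive noise of 0.5 % of
the curve range — representative of the replicate-averaged metric curves
the pipeline feeds the optimizer — the rule recovers the true half-slope
point within two grid steps in ≥95 % of cases.

Per metric, the three per-region factors (CSF, GM, WM) are averaged; the
final optimized factor is the mean of the CNR- and COV-derived factors
rounded to two decimals with half-away-from-zero rounding (so 0.245 →
0.25), matching the rounding convention of the published factor tables.

## Study pipeline and problem sizes

`run_full_study` chains simulation → optimization → denoising → metric
tables → NNPS. The pipeline defaults to 20 seeded noise replicates per
intensity so the optimizer curves and NNPS estimates are stable; metric
tables are computed from the first replicate (one image per condition, as
in a physical scan), while NNPS averages over all replicates and the four
corner air regions. `StudyConfig.desk_scale()` is the package's standard
desk-scale configuration: a 256×256 phantom at 1 mm spacing (identical
physical geometry to the 512×512 default), the full 100-point d sweep,
five intensities, 20 replicates — it runs in about a minute on one CPU and
is what the acceptance script and the end-to-end tests execute. All
randomness flows from a single seed; reruns are bit-identical, and outputs
carry a config hash plus the derived noise seeds.

## Known limitations

* Noise is white; real CT noise is correlated by the reconstruction kernel,
  so absolute CNR/COV/NNPS values and the exact optimized factors on
  scanner data will differ (the bundled reference tables measured on the
  physical phantom serve as that anchor). The qualitative findings — the
  optimized d grows with noise level, FNLM dominates Gaussian/Wiener/TV on
  every metric — are reproduced synthetically.
* The squared-mean NNPS normalization is ill-posed for true air; the
  bulk-mean fallback makes the curves comparable across algorithms but not
  directly comparable to detector-standard NNPS magnitudes.
* No volumetric (3-D) NLM, no GPU path, no adaptive (noise-estimating)
  parameter selection; the sweep is exhaustive by design.
* Bone/metal regions are not evaluated; the bronze insert exists only to
  complete the geometry.
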