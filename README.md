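# ctdenoise

Noise in CT images — especially low-dose CT — degrades diagnostic accuracy.
`ctdenoise` is a Python toolkit for studying and optimizing **fast non-local
means (FNLM)** denoising of CT images, built around a digital replica of a
3D-printed cylindrical brain phantom: a 16 cm case holding five 2.5 cm
inserts whose linear attenuation coefficients mimic cerebrospinal fluid
(0.208 cm⁻¹), gray matter (0.213 cm⁻¹), white matter (0.214 cm⁻¹), air, and
bone (bronze, 0.839 cm⁻¹).

It is aimed at medical-physics and image-processing researchers who want a
reproducible, fully synthetic pipeline: simulate the phantom slice, inject
Gaussian noise at controlled intensities, denoise (FNLM, Gaussian, adaptive
Wiener, total variation), score image quality (CNR, COV, NNPS), and derive
the noise-level-dependent optimal FNLM smoothing factor.

## The method

Non-local means replaces each pixel value I(m) by a similarity-weighted
average over a search window:

    NL[I](m) = Σₙ ω(m,n) I(n),      ω(m,n) = exp(−D(m,n)/d²) / Z(m),
    D(m,n)   = Σ_τ G_σ(τ) ‖I(m+τ) − I(n+τ)‖²,

where τ ranges over patch offsets, G_σ is a normalized Gaussian patch
weighting, d is the *smoothing factor*, and Z(m) normalizes the weights.
The fast variant (FNLM) computes the same weights with one-dimensional
cumulative sums of shifted squared-difference images, making the per-pixel
cost independent of the patch size; a brute-force NLM implementation is kept
as the numerical oracle (agreement < 1e−10).

Image quality is scored with

* **CNR** = (S_R − S_BK) / √(σ_R² + σ_BK²) between a material ROI and its
  background,
* **COV** = σ_R / μ_R within a material ROI,
* **NNPS**: tile-averaged |DFT|²·ΔxΔy/(N_xN_y) of the detrended air region,
  divided by the squared large-area mean signal (units mm²).

The optimal d per noise intensity follows the **half-slope rule**: sweep d
over 0.01…1.00, build the CNR(d) and COV(d) curves per tissue region, find
the smallest d at which each curve's slope magnitude has persistently fallen
to half its maximum, average over regions per metric, then average the CNR-
and COV-derived factors (rounded to two decimals).

## Worked example

```python
import ctdenoise as cd

spec = cd.PhantomSpec(matrix_size=256, pixel_spacing=1.0)
clean = cd.generate_phantom(spec)
layout = cd.default_roi_layout(spec)
noisy = [cd.add_gaussian_noise(clean, cd.NoiseSpec(intensity=0.01, seed=s))
         for s in range(5)]

opt = cd.SmoothingFactorOptimizer().fit(noisy, layout)
print(f"d_cnr={opt.d_cnr_:.3f} d_cov={opt.d_cov_:.3f} d_opt={opt.d_opt_}")

denoised = cd.FastNLMeansDenoiser(d=opt.d_opt_).fit().transform(noisy[0])
print("CNR CSF noisy :", round(cd.cnr(noisy[0], layout["CSF"], layout.background_for("CSF")), 3))
print("CNR CSF FNLM  :", round(cd.cnr(denoised, layout["CSF"], layout.background_for("CSF")), 3))
```

prints

```
d_cnr=0.257 d_cov=0.100 d_opt=0.18
CNR CSF noisy : 0.128
CNR CSF FNLM  : 0.883
```

i.e. at noise intensity (variance) 0.01 the optimizer selects d = 0.18, and
denoising at that factor raises the CSF-region contrast-to-noise ratio about
sevenfold. The same pipeline end-to-end:

```bash
ctdenoise optimize --noise 0.001 --noise 0.01 --noise 0.1 --out factors.json
ctdenoise run-all --out study_out/
```

The package also bundles the reference CNR/COV tables measured on scanner CT
images of the physical phantom (`ctdenoise.load_reference_table`), from
which improvement-ratio summaries are computed — e.g. optimized FNLM
improves CNR over the noisy image by factors between ×6.54 and ×16.34.

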