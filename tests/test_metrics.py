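"""CNR/COV/NNPS metric definitions and their closed-form checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctdenoise import (
    ImageGrid,
    NoiseSpec,
    ROI,
    add_gaussian_noise,
    cnr,
    cov,
    fnlm_denoise,
    nnps,
    nps_2d,
    radial_average,
    roi_stats,
)


def _grid(values, dx=1.0):
    return ImageGrid(np.asarray(values, dtype=float), dx=dx, dy=dx)


# -- ROI statistics ---------------------------------------------------------------


def test_roi_stats_population_convention():
    img = _grid([[0.0, 0.0], [1.0, 1.0]])
    s = roi_stats(img, ROI(0, 0, 2, 2, label="x"))
    assert s.mean == 0.5
    assert s.sd == 0.5  # divisor n, not n-1
    assert s.n == 4


def test_roi_out_of_bounds_rejected():
    img = _grid(np.zeros((8, 8)))
    with pytest.raises(ValueError, match="outside"):
        roi_stats(img, ROI(6, 6, 4, 4, label="oob"))


# -- CNR --------------------------------------------------------------------------


def test_cnr_hand_computed_value():
    # material: mean 10, sd 3; background: mean 6, sd 4 -> (10-6)/sqrt(25) = 0.8
    img = _grid(
        [
            [13.0, 7.0, 10.0, 2.0],
            [7.0, 13.0, 2.0, 10.0],
        ]
    )
    mat = ROI(0, 0, 2, 2, role="material", label="m")
    bg = ROI(0, 2, 2, 2, role="background", label="b")
    assert cnr(img, mat, bg) == pytest.approx(0.8, abs=1e-12)
    assert cnr(img, bg, mat) == pytest.approx(-0.8, abs=1e-12)  # sign preserved


def test_cnr_zero_for_equal_means(rng):
    vals = rng.normal(0.5, 0.1, size=(4, 8))
    vals[:, 4:] = vals[:, :4]
    img = _grid(vals)
    assert cnr(img, ROI(0, 0, 4, 4, label="a"), ROI(0, 4, 4, 4, label="b")) == pytest.approx(0.0)


def test_cnr_undefined_for_two_constant_rois():
    img = _grid(np.full((4, 8), 0.2))
    with pytest.raises(ValueError, match="constant"):
        cnr(img, ROI(0, 0, 4, 4, label="a"), ROI(0, 4, 4, 4, label="b"))


@given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1))
def test_cnr_invariant_under_affine_remap(a, b, seed):
    vals = np.random.default_rng(seed).normal(0.5, 0.1, size=(6, 12))
    mat, bg = ROI(0, 0, 6, 6, label="m"), ROI(0, 6, 6, 6, label="b")
    base = cnr(_grid(vals), mat, bg)
    assert cnr(_grid(a * vals + b), mat, bg) == pytest.approx(base, abs=1e-9, rel=1e-9)


# -- COV --------------------------------------------------------------------------


def test_cov_hand_computed_value():
    img = _grid([[3.0, 3.0], [5.0, 5.0]])  # mean 4, sd 1
    assert cov(img, ROI(0, 0, 2, 2, label="m")) == pytest.approx(0.25, abs=1e-12)


def test_cov_zero_for_constant_roi():
    assert cov(_grid(np.full((4, 4), 0.3)), ROI(0, 0, 4, 4, label="m")) == 0.0


def test_cov_undefined_for_zero_mean():
    with pytest.raises(ValueError, match="zero mean"):
        cov(_grid(np.zeros((4, 4))), ROI(0, 0, 4, 4, label="m"))


@given(st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
def test_cov_invariant_under_positive_scaling(a, seed):
    vals = np.random.default_rng(seed).normal(0.5, 0.1, size=(6, 6))
    roi = ROI(0, 0, 6, 6, label="m")
    assert cov(_grid(a * vals), roi) == pytest.approx(cov(_grid(vals), roi), abs=1e-9, rel=1e-9)


# -- NNPS -------------------------------------------------------------------------


def _white_noise_images(v, n_images, side, seed, mu=0.5, dx=1.0):
    base = ImageGrid(np.full((side, side), mu), dx=dx, dy=dx)
    return [
        add_gaussian_noise(base, NoiseSpec(intensity=v, seed=seed + k, clip=False))
        for k in range(n_images)
    ]


def test_nnps_of_uniform_images_is_zero():
    imgs = [ImageGrid(np.full((64, 64), 0.5), dx=1.0, dy=1.0)]
    curve = nnps(imgs, ROI(0, 0, 64, 64, role="nnps", label="r"), roi_size=32, norm_reference=0.5)
    np.testing.assert_allclose(curve.nnps, 0.0, atol=1e-25)


def test_white_noise_nnps_level_and_parseval():
    """White noise of variance v: NNPS ≈ v·Δ²/μ² and ∬NPS du dv = tile variance."""
    v, mu, dx, side = 0.01, 0.5, 0.5, 160
    imgs = _white_noise_images(v, 10, side, seed=100, mu=mu, dx=dx)
    region = ROI(0, 0, side, side, role="nnps", label="r")
    spec = nps_2d(imgs, region, roi_size=64, overlap=0.5)
    assert spec.roi_count >= 100
    # Parseval: NPS integral equals the mean detrended tile variance within 2 %
    du = spec.fu[1] - spec.fu[0]
    integral = spec.values.sum() * du * du
    assert integral == pytest.approx(spec.mean_tile_variance, rel=0.02)
    # closed-form white-noise level within 5 %
    mean_nnps = spec.values.ravel()[1:].mean() / mu**2
    assert mean_nnps == pytest.approx(v * dx * dx / mu**2, rel=0.05)


def test_white_noise_nnps_is_flat_across_bands():
    """High-frequency band mean within 10 % of low-frequency band mean at M ≥ 200."""
    imgs = _white_noise_images(0.01, 13, 160, seed=200)
    region = ROI(0, 0, 160, 160, role="nnps", label="r")
    curve = nnps(imgs, region, roi_size=64, overlap=0.5, norm_reference=0.5)
    assert curve.roi_count >= 200
    q = len(curve.freq) // 4
    ratio = curve.nnps[-q:].mean() / curve.nnps[:q].mean()
    assert 0.9 <= ratio <= 1.1


def test_nnps_rejects_near_zero_reference():
    imgs = _white_noise_images(0.01, 1, 64, seed=5, mu=0.0)
    with pytest.raises(ValueError, match="reference"):
        nnps(imgs, ROI(0, 0, 64, 64, role="nnps", label="r"), roi_size=32)


def test_nnps_region_smaller_than_tile_rejected():
    imgs = _white_noise_images(0.01, 1, 32, seed=5)
    with pytest.raises(ValueError, match="smaller than"):
        nnps(imgs, ROI(0, 0, 32, 32, role="nnps", label="r"), roi_size=64, norm_reference=0.5)


def test_nnps_max_frequency_bounded_by_nyquist():
    imgs = _white_noise_images(0.01, 1, 64, seed=6, dx=0.5)
    curve = nnps(imgs, ROI(0, 0, 64, 64, role="nnps", label="r"), roi_size=64, norm_reference=0.5)
    assert curve.freq.max() <= 1.0 / (2 * 0.5) + 1e-12
    assert np.all(np.diff(curve.freq) > 0) and np.all(curve.freq >= 0)


def test_radial_average_matches_naive_loop(rng):
    from ctdenoise.metrics import NPS2D

    side = 32
    vals = rng.uniform(size=(side, side))
    fu = np.fft.fftfreq(side, d=1.0)
    spec = NPS2D(values=vals, fu=fu, fv=fu, roi_count=1, roi_size=side, mean_tile_variance=0.0)
    freq, binned = radial_average(spec, n_bins_to_nyquist=16)
    # naive per-pixel binning oracle
    nyq = 0.5
    width = nyq / 16
    sums = np.zeros(16)
    counts = np.zeros(16)
    for i in range(side):
        for j in range(side):
            if i == 0 and j == 0:
                continue
            r = np.hypot(fu[i], fu[j])
            if r > nyq + 1e-12:
                continue
            b = min(int(r / width), 15)
            sums[b] += vals[i, j]
            counts[b] += 1
    keep = counts > 0
    np.testing.assert_allclose(binned, sums[keep] / counts[keep], atol=1e-12)
    np.testing.assert_allclose(freq, ((np.arange(16) + 0.5) * width)[keep], atol=1e-12)


def test_radial_average_of_constant_spectrum_is_constant():
    from ctdenoise.metrics import NPS2D

    fu = np.fft.fftfreq(64, d=1.0)
    spec = NPS2D(np.full((64, 64), 3.14), fu, fu, 1, 64, 0.0)
    _, binned = radial_average(spec)
    np.testing.assert_allclose(binned, 3.14, atol=1e-12)


def test_radially_quadratic_spectrum_bins_to_bin_center_squared():
    fu = np.fft.fftfreq(64, d=1.0)
    from ctdenoise.metrics import NPS2D

    r2 = fu[:, None] ** 2 + fu[None, :] ** 2
    spec = NPS2D(r2, fu, fu, 1, 64, 0.0)
    freq, binned = radial_average(spec)
    # bin means track r² at the bin center to within the bin width effect
    width = 0.5 / 64
    assert np.all(np.abs(np.sqrt(binned) - freq) < 2 * width + 1e-9)


def test_air_nnps_integral_nonincreasing_with_fnlm_smoothing(small_clean, small_layout):
    noisy = add_gaussian_noise(small_clean, NoiseSpec(intensity=0.05, seed=11))
    region = small_layout.by_role("nnps")[0]
    integrals = []
    for d in (0.05, 0.2, 0.6):
        den = fnlm_denoise(noisy, d=d, patch_radius=1, search_radius=3)
        spec = nps_2d(den, region, roi_size=32)
        du = spec.fu[1] - spec.fu[0]
        integrals.append(spec.values.sum() * du * du)
    assert np.all(np.diff(integrals) <= 1e-15)
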