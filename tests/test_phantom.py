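"""Phantom rasterization and Gaussian noise injection."""

import numpy as np
import pytest

from ctdenoise import (
    ImageGrid,
    Insert,
    MaterialDef,
    NoiseSpec,
    PhantomSpec,
    TABLE_MATERIALS,
    add_gaussian_noise,
    default_roi_layout,
    generate_phantom,
)
from ctdenoise.phantom import PhantomGeometryError, ROILayoutError, _pixel_centers


def _center_pixel(spec, ins):
    row, col = spec.to_pixel(*ins.center)
    return int(round(row)), int(round(col))


@pytest.mark.parametrize(
    "name,mu", [("XT-CF20", 0.208), ("wood", 0.213), ("air", 0.0), ("ABS", 0.214), ("bronze", 0.839)]
)
def test_insert_center_pixels_carry_material_attenuation(name, mu):
    spec = PhantomSpec()
    img = generate_phantom(spec)
    ins = next(i for i in spec.inserts if i.material.name == name)
    r, c = _center_pixel(spec, ins)
    assert img.values[r, c] == pytest.approx(mu, abs=0)


def test_empty_insert_list_gives_uniform_case_interior():
    spec = PhantomSpec(matrix_size=128, pixel_spacing=2.0, inserts=[])
    img = generate_phantom(spec)
    x, y = _pixel_centers(spec)
    interior = x**2 + y**2 <= (spec.case_outer_diameter / 2) ** 2
    assert np.all(img.values[interior] == spec.background_mu)
    assert np.all(img.values[~interior] == spec.air_mu)


def test_air_insert_pixel_count_matches_center_inside_oracle():
    """Rasterization uses the pixel-center-inside-circle rule, checked per pixel."""
    spec = PhantomSpec(
        matrix_size=128,
        pixel_spacing=0.5,
        case_outer_diameter=60.0,
        inserts=[Insert(TABLE_MATERIALS["air"], (10.0, -5.0), 25.0)],
    )
    img = generate_phantom(spec)
    n, d = spec.matrix_size, spec.pixel_spacing
    inside = in_case = 0
    for i in range(n):
        for j in range(n):
            x = (j + 0.5) * d - n * d / 2
            y = -((i + 0.5) * d - n * d / 2)
            if (x - 10.0) ** 2 + (y + 5.0) ** 2 <= 12.5**2:
                inside += 1
            if x * x + y * y <= 30.0**2:
                in_case += 1
    air_pixels_inside_case = int(np.sum(img.values == 0.0)) - (n * n - in_case)
    assert air_pixels_inside_case == inside


def test_case_interior_area_matches_circle_area_within_perimeter_band():
    spec = PhantomSpec(matrix_size=128, pixel_spacing=2.0, inserts=[])
    img = generate_phantom(spec)
    interior_px = int(np.sum(img.values == spec.background_mu))
    r_mm = spec.case_outer_diameter / 2
    expected = np.pi * r_mm**2 / (spec.pixel_spacing**2)
    band = np.pi * spec.case_outer_diameter / spec.pixel_spacing
    assert abs(interior_px - expected) <= band


@pytest.mark.parametrize(
    "inserts,err_fragment",
    [
        ([Insert(TABLE_MATERIALS["bronze"], (70.0, 0.0), 25.0)], "bronze"),
        (
            [
                Insert(TABLE_MATERIALS["wood"], (0.0, 0.0), 25.0),
                Insert(TABLE_MATERIALS["ABS"], (10.0, 0.0), 25.0),
            ],
            "overlap",
        ),
    ],
)
def test_invalid_geometry_raises_naming_the_insert(inserts, err_fragment):
    spec = PhantomSpec(inserts=inserts)
    with pytest.raises(PhantomGeometryError, match=err_fragment):
        generate_phantom(spec)


def test_fov_smaller_than_case_rejected():
    with pytest.raises(PhantomGeometryError, match="field of view"):
        generate_phantom(PhantomSpec(matrix_size=128, pixel_spacing=1.0))


# -- noise ------------------------------------------------------------------------


def test_zero_intensity_noise_is_identity(small_clean):
    out = add_gaussian_noise(small_clean, NoiseSpec(intensity=0.0, seed=3))
    np.testing.assert_array_equal(out.values, small_clean.values)


def test_noise_is_deterministic_given_seed(small_clean):
    a = add_gaussian_noise(small_clean, NoiseSpec(intensity=0.01, seed=42))
    b = add_gaussian_noise(small_clean, NoiseSpec(intensity=0.01, seed=42))
    c = add_gaussian_noise(small_clean, NoiseSpec(intensity=0.01, seed=43))
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_noise_sample_variance_matches_intensity_within_sampling_bounds():
    """Clip-free sampling check: variance of (noisy − clean) ≈ v within 3 SE."""
    v = 0.01
    base = ImageGrid(np.full((128, 128), 0.5), dx=1.0, dy=1.0)
    out = add_gaussian_noise(base, NoiseSpec(intensity=v, seed=7, clip=False))
    resid = out.values - base.values
    n = resid.size
    se = v * np.sqrt(2.0 / (n - 1))  # SE of a chi-square-distributed sample variance
    assert abs(resid.mean()) < 3 * np.sqrt(v / n)
    assert abs(resid.var() - v) < 3 * se


def test_clipping_keeps_values_in_unit_interval():
    base = ImageGrid(np.full((32, 32), 1.0), dx=1.0, dy=1.0)
    out = add_gaussian_noise(base, NoiseSpec(intensity=0.1, seed=0, clip=True))
    assert out.values.max() <= 1.0 and out.values.min() >= 0.0


def test_std_mode_interprets_intensity_as_sigma():
    base = ImageGrid(np.full((256, 256), 0.5), dx=1.0, dy=1.0)
    out = add_gaussian_noise(base, NoiseSpec(intensity=0.05, seed=1, mode="std", clip=False))
    assert abs((out.values - 0.5).std() - 0.05) < 0.002


def test_negative_intensity_rejected():
    with pytest.raises(ValueError, match="intensity"):
        NoiseSpec(intensity=-0.1)


# -- default ROI layout -----------------------------------------------------------


def test_default_layout_structure(small_spec, small_layout):
    assert len(small_layout.by_role("material")) == 3
    assert len(small_layout.by_role("background")) == 3
    assert len(small_layout.by_role("nnps")) >= 1
    assert len(small_layout.by_role("visual")) == 1
    small_layout.validate((small_spec.matrix_size, small_spec.matrix_size))


def test_material_rois_are_constant_on_clean_phantom(small_clean, small_layout):
    materials = {"CSF": 0.208, "GM": 0.213, "WM": 0.214}
    for label, mu in materials.items():
        patch = small_layout[label].extract(small_clean.values)
        assert np.all(patch == mu)
        bg = small_layout.background_for(label).extract(small_clean.values)
        assert np.all(bg == 0.190)


def test_roi_larger_than_insert_is_rejected(small_spec):
    with pytest.raises(ROILayoutError, match="does not fit"):
        default_roi_layout(small_spec, material_roi_size=15, nnps_roi_size=32)


def test_identical_spec_and_seed_give_bit_identical_images(small_spec):
    a = add_gaussian_noise(generate_phantom(small_spec), NoiseSpec(intensity=0.05, seed=9))
    b = add_gaussian_noise(generate_phantom(small_spec), NoiseSpec(intensity=0.05, seed=9))
    assert a.values.tobytes() == b.values.tobytes()
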