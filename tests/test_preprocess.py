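"""Preprocessing: spectral integration, automatic masks, cast correction, resize."""

import numpy as np
import pytest

from specreg.errors import DegenerateInputError
from specreg.preprocess import (
    HyperspectralCube,
    RGBImage,
    background_mask_from_intensity,
    correct_color_cast,
    estimate_background_color,
    he_background_mask,
    integral_intensity_image,
    resize_to_resolution,
)


def cube_from_spectrum(spectrum, wavenumbers, shape=(4, 5)):
    values = np.broadcast_to(np.asarray(spectrum, float), (*shape, len(spectrum))).copy()
    return HyperspectralCube(values, np.asarray(wavenumbers, float), pixel_size=5.0)


class TestIntegralIntensity:
    @pytest.mark.parametrize(
        "spectrum, wavenumbers, expected",
        [
            ([1.0, 1.0], [1000.0, 1001.0], 1.0),  # unit integrand, unit interval
            ([0.0, 0.0, 0.0], [1000.0, 1100.0, 1200.0], 0.0),
            ([0.0, 2.0, 0.0], [1000.0, 1001.0, 1002.0], 2.0),  # trapezoid by hand
        ],
    )
    def test_known_integrals(self, spectrum, wavenumbers, expected):
        img = integral_intensity_image(cube_from_spectrum(spectrum, wavenumbers))
        np.testing.assert_allclose(img, expected)
        assert img.shape == (4, 5)

    def test_single_band_rejected(self):
        with pytest.raises(DegenerateInputError, match="single-band"):
            integral_intensity_image(cube_from_spectrum([1.0], [1000.0]))


class TestIntensityMask:
    def test_bimodal_split(self):
        intensity = np.zeros((10, 10))
        intensity[:, 5:] = 10.0
        mask = background_mask_from_intensity(intensity)
        np.testing.assert_array_equal(mask.mask, intensity == 10.0)

    def test_cutoff_between_modes(self):
        values = np.repeat([0.0, 1.0, 9.0, 10.0], 25).reshape(10, 10)
        mask = background_mask_from_intensity(values)
        # cutoff strictly between 1 and 9: exactly the two top groups survive
        assert mask.n_foreground == 50
        assert mask.mask[values >= 9].all() and not mask.mask[values <= 1].any()

    def test_scale_equivariance(self, rng):
        intensity = rng.gamma(2.0, 1.0, size=(40, 40))
        base = background_mask_from_intensity(intensity).mask
        for c in (0.1, 7.3, 1000.0):
            np.testing.assert_array_equal(
                background_mask_from_intensity(c * intensity).mask, base
            )

    def test_tissue_only_split_rejected_with_ratio_gate(self):
        # two tissue classes, no substrate: Otsu would split them, but the
        # "background" class absorbs far too much to be bare substrate
        tissue = np.repeat([300.0, 500.0], 50).reshape(10, 10)
        assert background_mask_from_intensity(tissue, max_background_ratio=0.3).mask.all()
        # a genuine substrate/tissue split passes the gate untouched
        real = np.repeat([15.0, 400.0], 50).reshape(10, 10)
        mask = background_mask_from_intensity(real, max_background_ratio=0.3)
        assert mask.n_foreground == 50

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError, match="degenerate"):
            background_mask_from_intensity(np.full((5, 5), 3.0))

    def test_matches_phantom_substrate(self, small_scene, small_pair):
        from specreg.synthetic import roi_true_labels

        cube, _ = small_pair
        mask = background_mask_from_intensity(integral_intensity_image(cube))
        np.testing.assert_array_equal(mask.mask, roi_true_labels(small_scene) > 0)


class TestBackgroundColor:
    def test_bright_plateau_recovered(self):
        img = np.full((20, 20, 3), (90, 60, 70), dtype=np.uint8)
        img[:2, :] = (200, 190, 210)  # brightest 10 %
        color = estimate_background_color(RGBImage(img, 1.0))
        np.testing.assert_allclose(color, (200, 190, 210))

    def test_white_region_recovered(self):
        img = np.full((20, 20, 3), (120, 80, 140), dtype=np.uint8)
        img[:4, :] = 255
        np.testing.assert_allclose(estimate_background_color(RGBImage(img, 1.0)), 255)

    def test_dark_image_rejected(self):
        img = np.full((10, 10, 3), 40, dtype=np.uint8)
        with pytest.raises(DegenerateInputError, match="no background"):
            estimate_background_color(RGBImage(img, 1.0))

    def test_phantom_cast_recovered(self):
        from specreg.synthetic import make_scene, render_pair

        scene = make_scene(5, slide_shape=(150, 200), roi_shape=(50, 60))
        _, slide = render_pair(scene)
        color = estimate_background_color(slide)
        np.testing.assert_allclose(color, scene.cast_color, atol=2.0)


class TestCastCorrection:
    def test_background_pixel_becomes_white(self):
        img = np.full((4, 4, 3), (180, 170, 190), dtype=np.uint8)
        out = correct_color_cast(RGBImage(img, 1.0), np.array([180.0, 170.0, 190.0]))
        assert (out.values == 255).all()

    def test_division_in_intensity_space(self):
        img = np.full((2, 2, 3), 128, dtype=np.uint8)
        out = correct_color_cast(
            RGBImage(img, 1.0), np.array([200.0, 200.0, 200.0]), white_snap_distance=0.0
        )
        assert (out.values == 163).all()  # round(255 * 128 / 200)

    def test_white_background_is_identity(self):
        img = np.array([[[0, 50, 100]]], dtype=np.uint8)
        out = correct_color_cast(RGBImage(img, 1.0), np.array([255.0, 255.0, 255.0]))
        np.testing.assert_array_equal(out.values, img)

    def test_idempotent_with_white_background(self, rng):
        img = rng.integers(0, 256, size=(10, 10, 3)).astype(np.uint8)
        once = correct_color_cast(RGBImage(img, 1.0), np.array([220.0, 210.0, 230.0]))
        twice = correct_color_cast(once, np.array([255.0, 255.0, 255.0]))
        np.testing.assert_array_equal(once.values, twice.values)

    def test_zero_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            correct_color_cast(
                RGBImage(np.zeros((2, 2, 3), np.uint8), 1.0), np.array([0.0, 200.0, 200.0])
            )


class TestResize:
    def test_exact_ratio_dimensions(self):
        img = RGBImage(np.zeros((100, 100, 3), np.uint8), pixel_size=1.0)
        out = resize_to_resolution(img, 5.0)
        assert out.shape == (20, 20) and out.pixel_size == 5.0

    def test_constant_image_stays_constant(self):
        img = RGBImage(np.full((30, 40, 3), 77, np.uint8), pixel_size=2.0)
        out = resize_to_resolution(img, 6.0)
        assert (out.values == 77).all() and out.shape == (10, 13)

    def test_checkerboard_averages_to_midgray(self):
        tile = np.indices((8, 8)).sum(0) % 2
        img = RGBImage((tile[..., None] * np.array([255, 255, 255])).astype(np.uint8), 1.0)
        out = resize_to_resolution(img, 2.0)
        assert np.abs(out.values.astype(float) - 127.5).max() <= 0.5

    def test_mean_preserved_within_one_level(self, rng):
        img = RGBImage(rng.integers(0, 256, size=(60, 60, 3)).astype(np.uint8), 1.0)
        out = resize_to_resolution(img, 3.0)
        assert abs(out.values.mean() - img.values.mean()) < 1.0

    def test_upscale_warns_and_uses_bicubic(self):
        img = RGBImage(np.zeros((10, 10, 3), np.uint8), pixel_size=4.0)
        with pytest.warns(UserWarning, match="bicubic"):
            out = resize_to_resolution(img, 2.0)
        assert out.shape == (20, 20)


class TestHEMask:
    def test_all_white_is_all_background(self):
        img = RGBImage(np.full((5, 5, 3), 255, np.uint8), 1.0)
        assert not he_background_mask(img).mask.any()

    def test_no_white_is_all_foreground(self):
        img = RGBImage(np.full((5, 5, 3), 254, np.uint8), 1.0)
        assert he_background_mask(img).mask.all()

    def test_phantom_substrate_recovered(self):
        from specreg.synthetic import make_scene, render_pair

        scene = make_scene(6, slide_shape=(150, 200), roi_shape=(50, 60), noise_sigma_rgb=1.0)
        _, slide = render_pair(scene)
        corrected = correct_color_cast(slide, estimate_background_color(slide))
        mask = he_background_mask(corrected)
        np.testing.assert_array_equal(mask.mask, scene.label_map != 0)
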