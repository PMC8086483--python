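"""Pre-processing chain: inversion, grayscale, tiling, filtering, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

from nlmstain.phantom import PhantomParams, generate_phantom_pair
from nlmstain.preprocessing import (
    PreprocessConfig,
    extract_patches,
    filter_background,
    filter_registration_artifacts,
    homogeneity_factor,
    invert_contrast,
    padding_fractions,
    preprocess_nlm,
    scale_to_model_range,
    stitch_patches,
    to_grayscale,
    unscale_from_model_range,
)
from nlmstain.types import MultimodalImage

uint8_images = hnp.arrays(np.uint8, st.tuples(st.integers(1, 12), st.integers(1, 12), st.just(3)))


class TestContrastInversion:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), (0, 0, 0)), ((10, 200, 128), (245, 55, 127)), ((0, 0, 0), (255, 255, 255))],
    )
    def test_pixel_arithmetic(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert tuple(invert_contrast(img)[0, 0]) == expected

    @settings(max_examples=30, deadline=None)
    @given(uint8_images)
    def test_involution(self, img):
        np.testing.assert_array_equal(invert_contrast(invert_contrast(img)), img)

    def test_rejects_non_8bit(self):
        with pytest.raises(TypeError):
            invert_contrast(np.zeros((2, 2, 3), dtype=np.float32))
        with pytest.raises(ValueError):
            invert_contrast(np.full((2, 2, 3), 300, dtype=np.int32))


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((128, 128, 128), 128), ((0, 0, 0), 0), ((255, 255, 255), 255), ((255, 0, 0), 76)],
    )
    def test_luma_weights(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert to_grayscale(img)[0, 0] == expected

    def test_requires_three_channels(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestPatches:
    def test_exact_tiling_512(self, rng):
        img = rng.integers(0, 256, (512, 512, 3), dtype=np.uint8)
        grid = extract_patches(img, 256)
        assert len(grid) == 4
        assert set(grid.origins) == {(0, 0), (0, 256), (256, 0), (256, 256)}
        assert grid.seam_rows == [256] and grid.seam_cols == [256]

    def test_single_patch(self, rng):
        img = rng.integers(0, 256, (256, 256, 3), dtype=np.uint8)
        assert len(extract_patches(img, 256)) == 1

    def test_reflection_padding_300(self, rng):
        img = rng.integers(0, 256, (300, 300, 3), dtype=np.uint8)
        grid = extract_patches(img, 256)
        assert len(grid) == 4
        assert grid.padded_shape == (512, 512)

    @pytest.mark.parametrize("shape", [(300, 300), (256, 256), (77, 501), (1, 1)])
    def test_stitch_is_exact_inverse(self, rng, shape):
        img = rng.integers(0, 256, shape + (3,), dtype=np.uint8)
        grid = extract_patches(img, 256)
        np.testing.assert_array_equal(stitch_patches(grid), img)

    def test_padding_fractions(self, rng):
        img = rng.integers(0, 256, (300, 300, 3), dtype=np.uint8)
        fr = padding_fractions(extract_patches(img, 256))
        assert fr[0] == 0.0
        # corner patch covers only 44x44 of real pixels
        assert fr[3] == pytest.approx(1 - (44 * 44) / 256**2)


class TestBackgroundFilter:
    def test_constant_patch_removed(self):
        patches = [np.full((32, 32, 3), 77, dtype=np.uint8)]
        kept, _ = filter_background(patches)
        assert kept == []
        assert homogeneity_factor(patches[0]) == 1.0

    def test_textured_crypt_patch_kept(self, phantom_pair_256):
        nlm, _, _ = phantom_pair_256
        patch = nlm.pixels[64:128, 64:128]
        assert homogeneity_factor(patch) <= 0.60
        kept, _ = filter_background([patch])
        assert len(kept) == 1

    def test_threshold_extremes(self, rng):
        patches = [rng.integers(0, 256, (16, 16, 3), dtype=np.uint8) for _ in range(5)]
        kept_all, _ = filter_background(patches, homogeneity_threshold=1.0)
        assert len(kept_all) == 5
        kept_none, _ = filter_background(patches, homogeneity_threshold=0.0)
        assert kept_none == []  # every patch has some mass at its median


class TestArtifactFilter:
    def test_keep_and_remove(self):
        pair = (np.zeros((8, 8, 3), np.uint8), np.zeros((8, 8, 3), np.uint8))
        clean = np.zeros((8, 8), bool)
        touched = clean.copy()
        touched[0, 0] = True
        kept, idx = filter_registration_artifacts([pair, pair], [clean, touched])
        assert idx == [0]

    def test_missing_mask_is_error(self):
        with pytest.raises(ValueError):
            filter_registration_artifacts([(None, None)], None)

    def test_all_border_warns_and_empties(self):
        pair = (np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4, 3), np.uint8))
        with pytest.warns(UserWarning):
            kept, _ = filter_registration_artifacts([pair], [np.ones((4, 4), bool)])
        assert kept == []


class TestModelRangeScaling:
    def test_endpoints_and_midpoint(self):
        vals = np.array([[[0, 128, 255]]], dtype=np.uint8)
        scaled = scale_to_model_range(vals)
        assert scaled[0, 0, 0] == -1.0
        assert scaled[0, 0, 2] == 1.0
        assert scaled[0, 0, 1] == pytest.approx(128 / 127.5 - 1, abs=1e-7)

    def test_round_trip_all_256_values(self):
        v = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_array_equal(unscale_from_model_range(scale_to_model_range(v)), v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scale_to_model_range(np.array([300]))


class TestNLMPreprocessing:
    def test_constant_image_passes_through(self):
        img = MultimodalImage(np.full((64, 64, 3), 90, dtype=np.uint8))
        out = preprocess_nlm(img, PreprocessConfig(patch_size=8))
        assert np.unique(out.pixels).tolist() == [90]

    def test_downsampling_factor_four(self, phantom_pair_256):
        nlm, _, _ = phantom_pair_256
        out = preprocess_nlm(nlm, PreprocessConfig(patch_size=32))
        assert out.shape == (64, 64)
        assert out.pixel_size_um == pytest.approx(nlm.pixel_size_um * 4)

    def test_small_output_warns(self):
        img = MultimodalImage(np.random.default_rng(0).integers(0, 256, (64, 64, 3), dtype=np.uint8))
        with pytest.warns(UserWarning):
            preprocess_nlm(img, PreprocessConfig(patch_size=256))

    def test_median_removes_impulse_noise(self, rng):
        # structured base + 1% salt; with downsampling/illumination/stretch
        # disabled the chain must equal the plain median-filter oracle
        base = np.repeat(rng.integers(40, 200, (16, 16), dtype=np.uint8), 4, axis=0)
        base = np.repeat(base, 4, axis=1)
        img = np.stack([base] * 3, axis=-1)
        salt = rng.random((64, 64)) < 0.01
        img[salt] = 255
        cfg = PreprocessConfig(downsample=1, illumination_sigma=0, stretch_percentiles=None, patch_size=8)
        out = preprocess_nlm(MultimodalImage(img), cfg)
        oracle = np.stack([ndimage.median_filter(img[..., c].astype(float), size=3) for c in range(3)], axis=-1)
        np.testing.assert_array_equal(out.pixels, np.clip(np.rint(oracle), 0, 255).astype(np.uint8))
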