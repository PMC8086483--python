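"""Metric correctness against independent brute-force oracles."""

import numpy as np
import pytest
from skimage.color import rgb2lab

from nlmstain.evaluation import (
    EvalConfig,
    background_mask,
    css,
    css_from_lab,
    evaluate_dataset,
    mse,
    ssim,
)


def brute_force_mse(x, y):
    total, n = 0.0, 0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            for c in range(3):
                total += (float(x[i, j, c]) - float(y[i, j, c])) ** 2
                n += 1
    return total / n


def brute_force_css(x, y, threshold=0.5):
    """Literal per-pixel loop over the thresholded A*/B* similarities."""
    lx, ly = rgb2lab(x / 255.0), rgb2lab(y / 255.0)
    channel_scores = []
    for ch in (1, 2):
        dists = [
            abs(lx[i, j, ch] - ly[i, j, ch]) for i in range(x.shape[0]) for j in range(x.shape[1])
        ]
        md = max(dists)
        if md == 0:
            channel_scores.append(1.0)
            continue
        acc = 0.0
        for d in dists:
            sim = 1.0 - d / md
            ind = 1.0 if sim > threshold else 0.0
            acc += ind * sim
        channel_scores.append(acc / len(dists))
    return sum(channel_scores) / 2.0


def global_ssim_by_hand(a, b, L=255.0):
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mx, my = a.mean(), b.mean()
    vx, vy = ((a - mx) ** 2).mean(), ((b - my) ** 2).mean()
    cov = ((a - mx) * (b - my)).mean()
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


class TestMSE:
    def test_identical_images_score_zero(self, rng):
        x = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert mse(x, x) == 0.0

    def test_full_scale_difference(self):
        x = np.zeros((4, 4, 3), np.uint8)
        y = np.full((4, 4, 3), 255, np.uint8)
        assert mse(x, y) == 255.0**2

    def test_single_differing_pixel(self):
        x = np.zeros((2, 2, 3), np.uint8)
        y = x.copy()
        y[0, 0, 1] = 3
        assert mse(x, y) == pytest.approx(9 / 12)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (5, 7, 3), dtype=np.uint8)
        assert mse(x, y) == pytest.approx(brute_force_mse(x, y), abs=1e-12)
        assert mse(x, y) == mse(y, x)

    def test_empty_mask_rejected(self, rng):
        x = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            mse(x, x, np.zeros((4, 4), bool))


class TestSSIM:
    def test_self_similarity_is_one(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        assert ssim(he.pixels, he.pixels) == pytest.approx(1.0, abs=1e-9)
        assert ssim(he.pixels, he.pixels, mode="global") == pytest.approx(1.0, abs=1e-9)

    def test_inverted_image_scores_negative(self, rng):
        x = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        assert ssim(x, 255 - x, mode="global") < 0.0

    def test_global_mode_matches_hand_formula_on_3x3(self, rng):
        x = rng.integers(0, 256, (3, 3, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (3, 3, 3), dtype=np.uint8)
        expected = np.mean(
            [global_ssim_by_hand(x[..., c].astype(float), y[..., c].astype(float)) for c in range(3)]
        )
        assert ssim(x, y, mode="global") == pytest.approx(expected, abs=1e-9)

    def test_shift_invariance_for_mean_matched_images(self, rng):
        x = rng.integers(40, 100, (16, 16, 3)).astype(np.uint8)
        y = np.ascontiguousarray(x[::-1])  # same values, same mean, different layout
        base = ssim(x, y, mode="global")
        shifted = ssim(x + 40, y + 40, mode="global")
        assert shifted == pytest.approx(base, abs=1e-6)

    def test_too_small_for_local_window(self, rng):
        x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            ssim(x, x, mode="local")


class TestCSS:
    def test_self_similarity_is_one(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        assert css(he.pixels, he.pixels) == 1.0

    def test_matches_brute_force_on_small_images(self, rng):
        for _ in range(5):
            x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
            y = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
            assert css(x, y) == pytest.approx(brute_force_css(x, y), abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        assert css(x, y) == pytest.approx(css(y, x), abs=1e-12)

    def test_low_similarity_pixels_contribute_zero(self):
        # one pixel at the max distance has Sim = 0 <= threshold -> excluded
        lab_x = np.zeros((1, 2, 3))
        lab_y = np.zeros((1, 2, 3))
        lab_y[0, 0, 1] = 10.0  # A* distance 10 (the max); other pixel 0
        val = css_from_lab(lab_x, lab_y, threshold=0.5)
        # A*: pixel sims (0, 1) -> indicator drops the 0 -> mean 0.5; B*: 1.0
        assert val == pytest.approx((0.5 + 1.0) / 2)

    def test_monotone_in_single_pixel_distance(self):
        # under the fixed-denominator convention a growing A* distance of one
        # pixel can only lower the score (per-pair max renormalizes the rest)
        rng = np.random.default_rng(2)
        lab_x = rng.uniform(-20, 20, (4, 4, 3))
        lab_y = lab_x + rng.uniform(-5, 5, (4, 4, 3))
        vals = []
        for bump in np.linspace(0, 30, 7):
            ly = lab_y.copy()
            ly[0, 0, 1] = lab_x[0, 0, 1] + 6 + bump
            vals.append(css_from_lab(lab_x, ly, max_dist="fixed"))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_range_and_threshold_bounds(self, rng):
        x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert 0.0 <= css(x, y) <= 1.0
        with pytest.raises(ValueError):
            css(x, y, threshold=1.5)


class TestBackgroundMask:
    def test_all_tissue_phantom_keeps_everything(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        m = background_mask(he.pixels, EvalConfig(background_tile=64))
        assert m.all()

    def test_blank_quadrant_is_masked(self):
        from nlmstain.phantom import PhantomParams, generate_phantom_pair

        params = PhantomParams(image_size=(128, 128), crypt_count=2, crypt_radius_range=(10, 16),
                               background_quadrant=0, noise_sigma=1.0, seed=8)
        _, he, labels, _ = generate_phantom_pair(params)
        m = background_mask(he.pixels, EvalConfig(background_tile=64))
        assert not m[:64, :64].any()
        assert m[64:, 64:].all()

    def test_disabled_mask_is_full(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        assert background_mask(he.pixels, EvalConfig(exclude_background=False)).all()


class TestEvaluateDataset:
    def test_identical_pairs_hit_baseline_row(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        rep = evaluate_dataset([(he.pixels, he.pixels)] * 3, EvalConfig(background_tile=64))
        assert rep.mean_mse == 0.0
        assert rep.mean_ssim == pytest.approx(1.0, abs=1e-9)
        assert rep.mean_css == 1.0

    def test_means_are_hand_averages(self, phantom_pair_256, rng, tmp_path):
        _, he, _ = phantom_pair_256
        noisy = np.clip(he.pixels.astype(int) + rng.integers(-20, 20, he.pixels.shape), 0, 255).astype(np.uint8)
        rep = evaluate_dataset([(he.pixels, he.pixels), (noisy, he.pixels)], EvalConfig(background_tile=64),
                               csv_path=tmp_path / "r.csv")
        assert rep.mean_mse == pytest.approx(np.mean([r["mse"] for r in rep.per_image]))
        assert (tmp_path / "r.csv").read_text().startswith("image,")

    def test_mismatched_pair_skipped_with_warning(self, phantom_pair_256):
        _, he, _ = phantom_pair_256
        with pytest.warns(UserWarning):
            rep = evaluate_dataset(
                [(he.pixels, he.pixels), (he.pixels[:128], he.pixels)], EvalConfig(background_tile=64)
            )
        assert len(rep.per_image) == 1
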