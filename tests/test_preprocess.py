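"""ROI masking, bounding-box cropping, normalization and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from nucat import preprocess
from nucat.preprocess import (AugmentationSpec, CircleSpec, EmptyRoiError,
                              IMAGENET_MEAN, IMAGENET_STD, apply_circular_roi,
                              augment, alpha_bounding_box, denormalize,
                              extract_visible_roi, normalize_for_model)


class TestCircularRoi:
    def test_circle_covering_whole_image_sets_all_alpha(self, rng):
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        out = apply_circular_roi(img, CircleSpec(10, 10, 100))
        assert (out[:, :, 3] == 255).all()
        assert np.array_equal(out[:, :, :3], img)

    def test_boundary_pixels_follow_euclidean_distance(self, rng):
        img = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        out = apply_circular_roi(img, CircleSpec(50, 50, 10))
        assert out[50, 61, 3] == 0    # distance 11 > radius
        assert out[50, 59, 3] == 255  # distance 9 <= radius
        assert out[60, 50, 3] == 255  # distance 10, on the boundary

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            CircleSpec(5, 5, 0)

    def test_circle_outside_image_is_empty_roi(self, rng):
        img = rng.integers(0, 256, (10, 10, 3), dtype=np.uint8)
        with pytest.raises(EmptyRoiError):
            apply_circular_roi(img, CircleSpec(100, 100, 2))

    def test_mask_matches_per_pixel_distance_oracle(self, rng):
        img = rng.integers(0, 256, (37, 53, 3), dtype=np.uint8)
        circle = CircleSpec(center_x=20.5, center_y=11.25, radius=9.7)
        out = apply_circular_roi(img, circle)
        for _ in range(200):
            r = int(rng.integers(0, 37))
            c = int(rng.integers(0, 53))
            d = np.hypot(r - circle.center_y, c - circle.center_x)
            assert (out[r, c, 3] == 255) == (d <= circle.radius)

    def test_idempotent_for_fixed_circle(self, rng):
        img = rng.integers(0, 256, (30, 30, 3), dtype=np.uint8)
        circle = CircleSpec(15, 15, 8)
        once = apply_circular_roi(img, circle)
        twice = apply_circular_roi(once[:, :, :3], circle)
        assert np.array_equal(once, twice)


class TestExtractVisibleRoi:
    def test_fully_opaque_224_is_identity(self, rng):
        rgb = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        rgba = np.dstack([rgb, np.full((224, 224), 255, np.uint8)])
        assert np.array_equal(extract_visible_roi(rgba), rgb)

    def test_bounding_box_matches_stated_extents(self):
        rgba = np.zeros((100, 100, 4), np.uint8)
        rgba[10:60, 20:90, 3] = 255
        assert alpha_bounding_box(rgba) == (10, 59, 20, 89)

    def test_all_transparent_raises(self):
        with pytest.raises(EmptyRoiError):
            extract_visible_roi(np.zeros((10, 10, 4), np.uint8))

    def test_output_is_always_224_rgb(self, rng):
        rgba = np.zeros((77, 131, 4), np.uint8)
        rgba[5:40, 10:100] = rng.integers(0, 256, (35, 90, 4), dtype=np.uint8)
        rgba[20, 20, 3] = 255  # guarantee at least one visible pixel
        out = extract_visible_roi(rgba)
        assert out.shape == (224, 224, 3)
        assert out.dtype == np.uint8

    def test_transparent_pixels_composite_to_black(self):
        rgba = np.full((224, 224, 4), 200, np.uint8)
        rgba[:, 112:, 3] = 0   # right half transparent ...
        rgba[:, 223, 3] = 255  # ... but last column visible, so the bbox
        # spans the full width and the transparent strip stays inside it
        out = extract_visible_roi(rgba)
        assert (out[:, 150] == 0).all()

    def test_bbox_matches_exhaustive_scan_on_random_masks(self, rng):
        for _ in range(25):
            h = int(rng.integers(5, 40))
            w = int(rng.integers(5, 40))
            rgba = np.zeros((h, w, 4), np.uint8)
            n_on = int(rng.integers(1, h * w // 2 + 1))
            idx = rng.choice(h * w, size=n_on, replace=False)
            rgba.reshape(-1, 4)[idx, 3] = rng.integers(1, 256, n_on)
            expected = None
            for r in range(h):
                for c in range(w):
                    if rgba[r, c, 3] > 0:
                        if expected is None:
                            expected = [r, r, c, c]
                        else:
                            expected[0] = min(expected[0], r)
                            expected[1] = max(expected[1], r)
                            expected[2] = min(expected[2], c)
                            expected[3] = max(expected[3], c)
            assert alpha_bounding_box(rgba) == tuple(expected)


class TestNormalize:
    def test_all_zero_image_maps_to_minus_mean_over_std(self):
        out = normalize_for_model(np.zeros((224, 224, 3), np.uint8))
        for c in range(3):
            expected = -IMAGENET_MEAN[c] / IMAGENET_STD[c]
            assert out[c] == pytest.approx(expected, abs=1e-6)

    def test_mean_valued_pixel_maps_to_zero(self):
        img = np.zeros((224, 224, 3), np.uint8)
        img[:, :, 0] = round(255 * IMAGENET_MEAN[0])
        out = normalize_for_model(img)
        assert abs(out[0, 0, 0]) < 0.01

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            normalize_for_model(np.zeros((100, 100, 3), np.uint8))

    def test_roundtrip_within_one_intensity_level(self, rng):
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        back = denormalize(normalize_for_model(img))
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 1


class TestAugment:
    def test_same_seed_is_bit_identical(self, rng):
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        spec = AugmentationSpec(seed=9)
        assert np.array_equal(augment(img, spec), augment(img, spec))

    def test_null_spec_is_identity(self, rng):
        img = rng.integers(0, 256, (224, 224, 3), dtype=np.uint8)
        spec = AugmentationSpec(hflip_prob=0, rotation_range=0, jitter_factor=0)
        assert np.array_equal(augment(img, spec), img)

    def test_flip_frequency_close_to_half(self, rng):
        """Empirical horizontal-flip rate over 10,000 draws within 0.5 +- 0.02."""
        img = np.zeros((4, 4, 3), np.uint8)
        img[:, 0, 0] = 255  # marker column to detect the flip
        spec = AugmentationSpec(hflip_prob=0.5, rotation_range=0, jitter_factor=0)
        gen = np.random.default_rng(31)
        flips = sum(augment(img, spec, gen)[0, 0, 0] == 0 for _ in range(10_000))
        assert abs(flips / 10_000 - 0.5) <= 0.02

    def test_rotation_angle_drawn_uniform_in_range(self, rng):
        """The rotation draw is uniform(-range, +range) after the flip draw:
        reconstructing the documented draw order reproduces the output."""
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        spec = AugmentationSpec(hflip_prob=0.0, rotation_range=15.0,
                                jitter_factor=0.0, seed=123)
        oracle_rng = np.random.default_rng(123)
        oracle_rng.random()  # flip draw
        angle = oracle_rng.uniform(-15.0, 15.0)
        assert -15.0 <= angle <= 15.0
        expected = np.asarray(Image.fromarray(img, "RGB").rotate(
            angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0)))
        assert np.array_equal(augment(img, spec), expected)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_output_shape_and_dtype_preserved(self, seed):
        img = np.random.default_rng(1).integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = augment(img, AugmentationSpec(seed=seed))
        assert out.shape == img.shape and out.dtype == np.uint8
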