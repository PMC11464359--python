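"""Pixel-SVM counting: sampling, training, classification, components."""

import numpy as np
import pytest

from seedstand.svm_counter import (
    SOIL,
    SORGHUM,
    ComponentDetection,
    PixelSampleSet,
    build_samples,
    classify_pixels,
    count_components,
    merge_samples,
    min_area_for_altitude,
    opening_radius_for_altitude,
    patch_size_for_altitude,
    train_pixel_svm,
)
from seedstand.synthetic_field import SceneSpec, generate_scene


def cluster_samples(rng, n=200, separation=6.0):
    a = rng.normal(0, 1, size=(n, 3)) + (0, 0, 0)
    b = rng.normal(0, 1, size=(n, 3)) + (separation, separation, 0)
    return PixelSampleSet(
        features=np.vstack([a, b]),
        labels=np.concatenate([np.full(n, SOIL), np.full(n, SORGHUM)]),
        feature_names=("x", "y", "z"),
    )


class TestBuildSamples:
    def test_one_patch_per_class_row_count(self, small_scene, small_spec):
        img, truth, _ = small_scene
        samples = build_samples(img, truth, n_patches=1, patch_size=20, rng_seed=0)
        assert samples.features.shape == (2 * 400, 4)
        assert samples.labels.shape == (800,)
        assert set(np.unique(samples.labels)) <= {SOIL, SORGHUM}

    def test_empty_scene_raises(self):
        spec = SceneSpec(altitude_m=15, image_size=(120, 180), n_seedlings=0, rng_seed=3)
        img, truth = generate_scene(spec)
        with pytest.raises(ValueError):
            build_samples(img, truth, n_patches=1, patch_size=20, rng_seed=0)

    def test_same_seed_identical_samples(self, small_scene):
        img, truth, _ = small_scene
        s1 = build_samples(img, truth, n_patches=3, patch_size=16, rng_seed=7)
        s2 = build_samples(img, truth, n_patches=3, patch_size=16, rng_seed=7)
        np.testing.assert_array_equal(s1.features, s2.features)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_refined_plant_patches_contain_both_labels(self, small_scene):
        """A bounding-box patch spans leaves and inter-leaf soil; refinement
        should label the soil pixels as soil."""
        img, truth, _ = small_scene
        samples = build_samples(img, truth, n_patches=4, patch_size=16, rng_seed=0)
        fg_labels = samples.labels[: 4 * 256]
        assert (fg_labels == SORGHUM).any()
        assert (fg_labels == SOIL).any()


class TestTraining:
    def test_separable_clusters_perfect_training_accuracy(self, rng):
        samples = cluster_samples(rng)
        model = train_pixel_svm(samples)
        acc = (model.pipeline.predict(samples.features) == samples.labels).mean()
        assert acc == 1.0

    def test_permuted_labels_chance_accuracy(self, rng):
        samples = cluster_samples(rng, n=400)
        shuffled = samples.labels.copy()
        rng.shuffle(shuffled)
        model = train_pixel_svm(
            PixelSampleSet(samples.features, shuffled, samples.feature_names)
        )
        acc = (model.pipeline.predict(samples.features) == shuffled).mean()
        assert acc == pytest.approx(0.5, abs=0.1)

    def test_single_class_raises(self, rng):
        samples = cluster_samples(rng)
        bad = PixelSampleSet(
            samples.features, np.full_like(samples.labels, SOIL), samples.feature_names
        )
        with pytest.raises(ValueError):
            train_pixel_svm(bad)

    def test_duplicating_samples_preserves_margin(self, rng):
        """For a separable problem the maximum-margin boundary is set by the
        support vectors, so duplicating every sample leaves it unchanged."""
        samples = cluster_samples(rng, separation=8.0)
        doubled = merge_samples([samples, samples])
        # large C ⇒ hard margin on this separable problem, so the solution
        # is pinned by the support vectors alone
        m1 = train_pixel_svm(samples, C=100.0)
        m2 = train_pixel_svm(doubled, C=100.0)
        grid = rng.normal(4, 3, size=(50, 3))
        d1 = m1.pipeline.decision_function(grid)
        d2 = m2.pipeline.decision_function(grid)
        np.testing.assert_allclose(d1, d2, rtol=1e-3, atol=1e-3)


class TestClassifyPixels:
    def test_training_scene_mask_iou(self, small_scene):
        img, truth, true_mask = small_scene
        samples = build_samples(img, truth, n_patches=8, patch_size=16, rng_seed=0)
        model = train_pixel_svm(samples)
        pred = classify_pixels(model, img)
        inter = (pred & true_mask).sum()
        union = (pred | true_mask).sum()
        assert inter / union >= 0.9

    def test_all_soil_image_mostly_background(self, small_scene):
        img, truth, _ = small_scene
        samples = build_samples(img, truth, n_patches=8, patch_size=16, rng_seed=0)
        model = train_pixel_svm(samples)
        soil_spec = SceneSpec(
            altitude_m=15, image_size=(200, 200), n_seedlings=0, weed_density=0, rng_seed=5
        )
        soil_img, _ = generate_scene(soil_spec)
        assert classify_pixels(model, soil_img).mean() < 0.05

    def test_repeated_calls_identical(self, small_scene):
        img, truth, _ = small_scene
        samples = build_samples(img, truth, n_patches=4, patch_size=16, rng_seed=0)
        model = train_pixel_svm(samples)
        np.testing.assert_array_equal(classify_pixels(model, img), classify_pixels(model, img))


def two_squares(bridge=False):
    mask = np.zeros((20, 30), dtype=bool)
    mask[5:10, 5:10] = True
    mask[5:10, 15:20] = True
    if bridge:
        mask[7, 10:15] = True
    return mask


class TestCountComponents:
    def test_two_disjoint_squares(self):
        count, dets = count_components(two_squares(), min_area_px=4, opening_radius=0)
        assert count == 2 == len(dets)
        assert all(d.area_px == 25 for d in dets)
        assert all(d.confidence == 1.0 for d in dets)

    def test_min_area_filters_everything(self):
        count, dets = count_components(two_squares(), min_area_px=26, opening_radius=0)
        assert count == 0 and dets == []

    def test_opening_severs_one_pixel_bridge(self):
        bridged = two_squares(bridge=True)
        count_raw, _ = count_components(bridged, min_area_px=4, opening_radius=0)
        assert count_raw == 1
        count, _ = count_components(bridged, min_area_px=4, opening_radius=1)
        assert count == 2

    def test_non_boolean_input_raises(self):
        with pytest.raises(TypeError):
            count_components(np.zeros((5, 5), dtype=np.uint8))

    def test_boxes_within_bounds_and_consistent(self, small_scene):
        img, truth, mask = small_scene
        count, dets = count_components(mask, min_area_px=10, opening_radius=0)
        assert count == len(dets)
        h, w = mask.shape
        for d in dets:
            x1, y1, x2, y2 = d.bbox
            assert 0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h
            assert 0 < d.confidence <= 1.0
            assert d.area_px <= (x2 - x1) * (y2 - y1)

    def test_count_monotone_in_min_area(self, rng):
        mask = rng.random((60, 60)) < 0.3
        counts = [
            count_components(mask, min_area_px=a, opening_radius=0)[0]
            for a in (1, 2, 4, 8, 16, 32)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAltitudeScaling:
    def test_min_area_quadratic_with_floor(self):
        assert min_area_for_altitude(36.0, 15.0) == 36.0
        assert min_area_for_altitude(36.0, 30.0) == 9.0
        assert min_area_for_altitude(36.0, 45.0) == 4.0  # floored
        assert min_area_for_altitude(36.0, 90.0) == 4.0

    def test_opening_radius_and_patch_linear(self):
        assert opening_radius_for_altitude(3, 15.0) == 3
        assert opening_radius_for_altitude(3, 45.0) == 1
        assert patch_size_for_altitude(20, 30.0) == 10
        assert patch_size_for_altitude(20, 45.0) == 7
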