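"""Segmentation and measurement: nuclei, domes, mitochondria, puncta."""

import numpy as np
import pandas as pd
import pytest

from domescope.quantify import (
    ThresholdSpec,
    classify_enlarged,
    count_large_puncta,
    count_nuclei,
    enlarged_threshold_from_controls,
    extract_features,
    feature_names,
    segment_domes,
    segment_mitochondria,
    train_pixel_classifier,
)
from domescope.scene import ScenePars, generate_scene


class TestCountNuclei:
    def test_blank_image_counts_zero(self):
        n, cents = count_nuclei(np.zeros((64, 64)), 1.0)
        assert n == 0 and cents.shape == (0, 2)

    def test_well_separated_nuclei_counted_exactly(self):
        pars = ScenePars(field_size_um=512.0, n_planes=2, n_nuclei=100, seed=3)
        gt, _, ideal = generate_scene(pars)
        n, cents = count_nuclei(ideal["nuclear"], 1.0, min_area_um2=12.0)
        assert n == 100
        # centroids match ground truth within one nucleus radius
        d = np.sqrt(((cents[:, None] - gt.nuclei[None]) ** 2).sum(-1))
        assert d.min(axis=1).max() <= pars.nucleus_radius_um[1]

    def test_overlapping_pair_split_by_watershed(self):
        img = np.full((100, 100), 10.0)
        yy, xx = np.mgrid[0:100, 0:100]
        r = 10
        for cx in (40, 40 + int(1.7 * r)):  # overlap < 30% of radius
            img[(yy - 50) ** 2 + (xx - cx) ** 2 <= r * r] = 180.0
        n, _ = count_nuclei(img, 1.0, min_area_um2=12.0)
        assert n == 2


class TestSegmentDomes:
    def test_flat_height_map_finds_nothing(self):
        labels, area = segment_domes(np.zeros((64, 64)), 5.0, 100.0, 1.0)
        assert labels.n_objects == 0 and area == 0.0

    def test_raised_disc_area_within_five_percent(self):
        h = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2
        h[disc] = 10.0
        labels, area = segment_domes(h, 5.0, 100.0, 1.0)
        assert labels.n_objects == 1
        assert area == pytest.approx(np.pi * 50**2, rel=0.05)

    def test_disc_below_height_threshold_excluded(self):
        h = np.zeros((64, 64))
        h[20:40, 20:40] = 4.0
        _, area = segment_domes(h, 5.0, 10.0, 1.0)
        assert area == 0.0

    def test_total_area_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        h = np.zeros((128, 128))
        for cy, cx, r, top in [(30, 30, 15, 10.0), (90, 80, 25, 5.0)]:
            yy, xx = np.mgrid[0:128, 0:128]
            h[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = top
        areas_h = [segment_domes(h, mh, 10.0, 1.0)[1] for mh in (2.5, 5.0, 7.5)]
        assert areas_h == sorted(areas_h, reverse=True)
        areas_a = [segment_domes(h, 2.5, ma, 1.0)[1]
                   for ma in (10.0, 500.0, 1500.0)]
        assert areas_a == sorted(areas_a, reverse=True)
        del rng

    def test_no_modal_plateau_errors(self, rng):
        h = rng.random((64, 64)) * 30
        with pytest.raises(ValueError, match="smooth"):
            segment_domes(h, 5.0, 100.0, 1.0)


class TestFeaturesAndClassifier:
    def test_constant_image_has_zero_derivative_features(self):
        f = extract_features(np.full((32, 32), 9.0), scales=(1.0, 2.0))
        names = feature_names((1.0, 2.0))
        for i, name in enumerate(names):
            if "gaussian" not in name:
                # truncated discrete kernels leave ~1e-3 residuals
                assert np.abs(f[..., i]).max() <= 1e-2, name

    def test_feature_count_is_five_per_scale(self):
        f = extract_features(np.zeros((16, 16)), scales=(1.0, 2.0, 4.0))
        assert f.shape == (16, 16, 15)
        with pytest.raises(ValueError):
            extract_features(np.zeros((16, 16)), scales=())

    def test_shifted_image_gives_shifted_features(self, textured_image):
        img = textured_image[:64, :64]
        f1 = extract_features(img, scales=(1.0,))
        f2 = extract_features(np.roll(img, (4, 4), axis=(0, 1)), scales=(1.0,))
        inner = (slice(16, -16), slice(16, -16))
        assert np.allclose(np.roll(f1, (4, 4), axis=(0, 1))[inner], f2[inner],
                           atol=1e-8)

    @staticmethod
    def _toy_labeled(seed=0):
        rng = np.random.default_rng(seed)
        img = np.zeros((96, 96))
        yy, xx = np.mgrid[0:96, 0:96]
        for cx, cy in [(20, 20), (60, 30), (40, 70), (75, 75)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 < 64] = 200.0
        img += rng.normal(0, 2, img.shape)
        labels = np.zeros((96, 96), dtype=int)
        labels[img > 150] = 2
        labels[img < 50] = 1
        sparse = np.where(rng.random(img.shape) < 0.2, labels, 0)
        return img, sparse

    def test_separable_classes_learned_almost_perfectly(self):
        img, sparse = self._toy_labeled()
        model = train_pixel_classifier([img], [sparse], seed=0,
                                       scales=(1.0, 2.0))
        assert model.holdout_accuracy >= 0.99

    def test_same_seed_gives_identical_predictions(self):
        img, sparse = self._toy_labeled()
        m1 = train_pixel_classifier([img], [sparse], seed=4, scales=(1.0,))
        m2 = train_pixel_classifier([img], [sparse], seed=4, scales=(1.0,))
        probe, _ = self._toy_labeled(seed=9)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))

    def test_single_class_or_sparse_class_rejected(self):
        img, sparse = self._toy_labeled()
        only_one = np.where(sparse == 2, 2, 0)
        with pytest.raises(ValueError, match="2 labeled classes"):
            train_pixel_classifier([img], [only_one], seed=0, scales=(1.0,))
        few = sparse.copy()
        idx = np.argwhere(few == 1)
        few[tuple(idx[30:].T)] = 0  # leave < 50 labels of class 1
        with pytest.raises(ValueError, match="class 1"):
            train_pixel_classifier([img], [few], seed=0, scales=(1.0,))


class TestMitochondria:
    def test_blank_channel_gives_empty_result(self):
        lm, table, fp = segment_mitochondria(
            np.zeros((64, 64)), 0.1, threshold=ThresholdSpec("otsu")
        )
        assert fp == 0.0 and len(table) == 0

    def test_known_mask_footprint_recovered(self):
        img = np.zeros((100, 100))
        img[:30, :40] = 200.0  # 1200 px = 12% of the field
        lm, table, fp = segment_mitochondria(
            img, 0.1, threshold=ThresholdSpec("fixed", 100.0)
        )
        assert fp == pytest.approx(0.12, abs=0.01)

    def test_object_areas_sum_to_footprint_exactly(self):
        pars = ScenePars(field_size_um=48.0, pixel_size_um=0.1, n_planes=2,
                         mito_density=8.0, seed=1)
        _, _, ideal = generate_scene(pars)
        lm, table, fp = segment_mitochondria(
            ideal["mito"], 0.1, threshold=ThresholdSpec("otsu")
        )
        field_area_um2 = ideal["mito"].size * 0.1**2
        assert table["area_um2"].sum() == pytest.approx(fp * field_area_um2)

    def test_model_and_threshold_are_exclusive(self):
        with pytest.raises(ValueError, match="exactly one"):
            segment_mitochondria(np.zeros((8, 8)), 0.1)


class TestClassifyEnlarged:
    def test_threshold_above_max_marks_none(self):
        tbl = pd.DataFrame({"area_um2": [1.0, 2.0, 3.0]})
        n, frac, _ = classify_enlarged(tbl, 10.0)
        assert n == 0 and frac == 0.0

    def test_median_threshold_on_odd_set_is_strict(self):
        areas = np.arange(1.0, 10.0)  # 9 objects, median 5
        tbl = pd.DataFrame({"area_um2": areas})
        n, frac, out = classify_enlarged(tbl, 5.0)
        assert n == 4  # strictly greater than the median
        assert (out["class"] == "enlarged").sum() == 4

    def test_empty_table_fraction_zero(self):
        n, frac, _ = classify_enlarged(pd.DataFrame({"area_um2": []}), 1.0)
        assert n == 0 and frac == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_enlarged(pd.DataFrame({"area_um2": [1.0]}), -1.0)

    def test_generator_fraction_recovered(self):
        pars = ScenePars(field_size_um=48.0, pixel_size_um=0.1, n_planes=2,
                         mito_density=15.0, enlarged_fraction=0.2, seed=5)
        gt, _, ideal = generate_scene(pars)
        _, table, _ = segment_mitochondria(
            ideal["mito"], 0.1, threshold=ThresholdSpec("otsu")
        )
        # threshold between the generator's regular and enlarged ranges
        n, frac, _ = classify_enlarged(table, 2.0)
        assert frac == pytest.approx(0.2, abs=0.05)

    def test_percentile_threshold_helper(self):
        areas = np.linspace(0.1, 2.0, 200)
        thr = enlarged_threshold_from_controls(areas, 97.5)
        assert (areas > thr).mean() == pytest.approx(0.025, abs=0.01)


class TestCountLargePuncta:
    def test_blank_image_counts_zero(self):
        assert count_large_puncta(np.zeros((64, 64)), 0.5, 4.0) == 0

    def test_only_puncta_above_min_area_counted(self):
        areas = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 1.0, 1.5, 2.0, 2.5, 3.0)
        pars = ScenePars(field_size_um=331.5, pixel_size_um=0.5, n_planes=2,
                         autophagosome_areas=areas, seed=7)
        _, _, ideal = generate_scene(pars)
        n = count_large_puncta(ideal["autophagosome"], 0.5, min_area_um2=4.0)
        assert n == 7

    def test_count_monotone_in_min_area(self):
        areas = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 1.0, 1.5, 2.0, 2.5, 3.0)
        pars = ScenePars(field_size_um=331.5, pixel_size_um=0.5, n_planes=2,
                         autophagosome_areas=areas, seed=7)
        _, _, ideal = generate_scene(pars)
        counts = [
            count_large_puncta(ideal["autophagosome"], 0.5, a)
            for a in (2.0, 4.0, 8.0, 16.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_quantile_validated(self):
        with pytest.raises(ValueError):
            count_large_puncta(np.zeros((8, 8)), 0.5, 1.0, intensity_quantile=1.5)
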