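import json

import numpy as np
import pytest

from itf import segmentation as seg
from itf.synthetic import FiberImageSpec, generate_fiber_image


class TestOpticalDensity:
    def test_identity_intensity_gives_zero(self):
        od = seg.optical_density(np.full((4, 4), 200.0), i0=200.0)
        assert od.values == pytest.approx(0.0)

    def test_tenth_intensity_gives_one(self):
        od = seg.optical_density(np.full((4, 4), 20.0), i0=200.0)
        assert od.values == pytest.approx(1.0)

    def test_zero_intensity_clipped_to_od_max(self):
        od = seg.optical_density(np.zeros((4, 4)), i0=200.0, od_max=3.0)
        assert od.values == pytest.approx(3.0)

    def test_invalid_i0(self):
        with pytest.raises(seg.ParameterError):
            seg.optical_density(np.ones((4, 4)), i0=0.0)

    def test_rgb_channel_average(self):
        img = np.stack(
            [np.full((3, 3), 20.0), np.full((3, 3), 200.0), np.full((3, 3), 200.0)], axis=-1
        )
        od = seg.optical_density(img, i0=np.array([200.0, 200.0, 200.0]))
        assert od.values == pytest.approx(1.0 / 3.0)
        assert od.channels.shape == (3, 3, 3)


class TestEnhancement:
    def test_flat_image_enhances_to_zero(self):
        od = seg.optical_density(np.full((64, 64), 200.0), i0=255.0)
        enh = seg.enhance_fibers(od, resolution=0.46)
        assert enh.values == pytest.approx(0.0, abs=1e-9)

    def test_bar_enhanced_above_background(self):
        img = np.full((128, 128), 220.0)
        img[60:66, 20:110] = 90.0
        od = seg.optical_density(img, i0=255.0)
        enh = seg.enhance_fibers(od, resolution=1.0, scales_um=(2.0, 3.0))
        bar = np.zeros_like(img, dtype=bool)
        bar[60:66, 20:110] = True
        assert enh.values[bar].mean() > 2 * enh.values[~bar].mean()

    def test_contrast_nondecreasing_with_iterations(self, small_fiber_image):
        od = seg.optical_density(small_fiber_image.image)
        contrasts = []
        for n_iter in (1, 2, 3):
            enh = seg.enhance_fibers(od, n_iter=n_iter, resolution=0.46)
            on = enh.values[small_fiber_image.truth_mask].mean()
            off = max(enh.values[~small_fiber_image.truth_mask].mean(), 1e-12)
            contrasts.append(on / off)
        assert contrasts[0] <= contrasts[1] <= contrasts[2]

    def test_empty_scales_rejected(self):
        od = seg.optical_density(np.full((32, 32), 100.0), i0=255.0)
        with pytest.raises(seg.ParameterError):
            seg.enhance_fibers(od, scales_um=())


class TestPixelFeatures:
    def test_constant_image_zero_sd(self):
        od = seg.optical_density(np.full((32, 32), 150.0), i0=255.0)
        feats = seg.pixel_features(od, od, window_px=9)
        sd_idx = seg.FEATURE_NAMES.index("local_sd")
        assert feats[..., sd_idx] == pytest.approx(0.0, abs=1e-6)

    def test_feature_count(self, small_fiber_image):
        od = seg.optical_density(small_fiber_image.image)
        enh = seg.enhance_fibers(od, resolution=0.46)
        feats = seg.pixel_features(od, enh)
        assert feats.shape[-1] == len(seg.FEATURE_NAMES) == 6

    def test_features_finite(self, small_fiber_image):
        od = seg.optical_density(small_fiber_image.image)
        enh = seg.enhance_fibers(od, resolution=0.46)
        feats = seg.pixel_features(od, enh)
        assert np.isfinite(feats).all()

    def test_window_validation(self):
        od = seg.optical_density(np.full((32, 32), 150.0), i0=255.0)
        with pytest.raises(seg.ParameterError):
            seg.pixel_features(od, od, window_px=4)
        with pytest.raises(seg.ParameterError):
            seg.pixel_features(od, od, window_px=99)


def _toy_features(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.5
    x = np.where(y, 1.0, 0.0)[:, None] + rng.normal(0, 0.01, (n, 1))
    feats = np.concatenate([x, rng.normal(size=(n, 1))], axis=1)
    return feats.reshape(n, 1, 2), y.reshape(n, 1)


class TestLogitModel:
    def test_separable_training_auc_one(self):
        feats, y = _toy_features()
        model = seg.fit_pixel_logit(feats, y, n_sample=200, seed=0, feature_names=("a", "b"))
        prob = seg.probability_map(model, feats, feature_names=("a", "b"))
        assert seg.roc_auc(prob, y) == 1.0

    def test_separable_weight_sign(self):
        feats, y = _toy_features()
        model = seg.fit_pixel_logit(feats, y, n_sample=200, seed=0, feature_names=("a", "b"))
        assert model.weights[0] > 0

    def test_fit_determinism(self):
        feats, y = _toy_features()
        m1 = seg.fit_pixel_logit(feats, y, n_sample=100, seed=5, feature_names=("a", "b"))
        m2 = seg.fit_pixel_logit(feats, y, n_sample=100, seed=5, feature_names=("a", "b"))
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.intercept == m2.intercept

    def test_single_class_raises(self):
        feats, y = _toy_features()
        with pytest.raises(seg.DegenerateTrainingError):
            seg.fit_pixel_logit(feats, np.zeros_like(y), feature_names=("a", "b"))

    def test_json_round_trip_preserves_predictions(self):
        feats, y = _toy_features()
        model = seg.fit_pixel_logit(feats, y, n_sample=200, seed=0, feature_names=("a", "b"))
        restored = seg.LogitModel.from_json(model.to_json())
        p1 = seg.probability_map(model, feats, feature_names=("a", "b"))
        p2 = seg.probability_map(restored, feats, feature_names=("a", "b"))
        assert np.array_equal(p1, p2)


class TestProbabilityMap:
    def _zero_model(self):
        return seg.LogitModel(
            feature_names=("a", "b"),
            weights=np.zeros(2),
            intercept=0.0,
            scale_mean=np.zeros(2),
            scale_sd=np.ones(2),
        )

    def test_zero_weights_give_half(self, rng):
        model = self._zero_model()
        feats = rng.normal(size=(5, 5, 2))
        assert seg.probability_map(model, feats, ("a", "b")) == pytest.approx(0.5)

    def test_large_negative_intercept_limit(self, rng):
        model = self._zero_model()
        model.intercept = -800.0
        p = seg.probability_map(model, rng.normal(size=(3, 3, 2)), ("a", "b"))
        assert p == pytest.approx(0.0, abs=1e-300)

    def test_monotone_in_positive_weight(self):
        model = self._zero_model()
        model.weights = np.array([2.0, 0.0])
        grid = np.linspace(-3, 3, 50)
        feats = np.stack([grid, np.zeros(50)], axis=-1).reshape(50, 1, 2)
        p = seg.probability_map(model, feats, ("a", "b")).ravel()
        assert np.all(np.diff(p) > 0)

    def test_feature_permutation_invariance(self, rng):
        feats = rng.normal(size=(8, 8, 2))
        model = seg.LogitModel(
            feature_names=("a", "b"),
            weights=np.array([1.5, -0.7]),
            intercept=0.3,
            scale_mean=np.array([0.1, 0.2]),
            scale_sd=np.array([1.0, 2.0]),
        )
        p_ab = seg.probability_map(model, feats, ("a", "b"))
        p_ba = seg.probability_map(model, feats[..., ::-1], ("b", "a"))
        assert p_ab == pytest.approx(p_ba, abs=1e-15)

    def test_mismatched_names_raise(self, rng):
        model = self._zero_model()
        with pytest.raises(KeyError):
            seg.probability_map(model, rng.normal(size=(2, 2, 2)), ("x", "y"))


def _flood_fill_count(mask):
    """Independent 8-connected component count via explicit BFS."""
    mask = mask.copy()
    count = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            count += 1
            stack = [(i, j)]
            mask[i, j] = False
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
    return count


class TestSegmentFibers:
    def test_all_zero_prob(self):
        fs = seg.segment_fibers(np.zeros((32, 32)), 0.5, 10.0, 1.0)
        assert fs.n_fibers == 0

    def test_two_blobs_flood_fill_oracle(self):
        prob = np.zeros((40, 40))
        prob[5:12, 5:12] = 0.9
        prob[25:33, 20:30] = 0.8
        fs = seg.segment_fibers(prob, 0.5, 10.0, 1.0)
        assert fs.n_fibers == _flood_fill_count(prob >= 0.5) == 2

    def test_min_area_filter(self):
        prob = np.zeros((40, 40))
        prob[5:7, 5:7] = 0.9  # 4 px < 10 um^2 at r=1
        prob[20:30, 20:30] = 0.9
        fs = seg.segment_fibers(prob, 0.5, 10.0, 1.0)
        assert fs.n_fibers == 1

    def test_labels_contiguous(self, rng):
        prob = (rng.random((64, 64)) > 0.7).astype(float)
        fs = seg.segment_fibers(prob, 0.5, 2.0, 1.0)
        labels = np.unique(fs.labels)
        assert labels[0] == 0
        assert list(labels[1:]) == list(range(1, fs.n_fibers + 1))

    def test_threshold_monotonicity(self, rng):
        prob = rng.random((64, 64))
        areas = [
            (seg.segment_fibers(prob, t, 0.0 + 1e-9, 1.0).labels > 0).sum()
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert areas == sorted(areas, reverse=True)

    def test_invalid_threshold(self):
        with pytest.raises(seg.ParameterError):
            seg.segment_fibers(np.zeros((4, 4)), 0.0, 1.0, 1.0)


class TestEndToEnd:
    def test_synthetic_auc_and_component_recovery(self):
        train = generate_fiber_image(FiberImageSpec(width_px=512, height_px=512, n_fibers=20, seed=21))
        test = generate_fiber_image(FiberImageSpec(width_px=512, height_px=512, n_fibers=20, seed=22))

        def features(im):
            od = seg.optical_density(im.image)
            enh = seg.enhance_fibers(od, resolution=0.46)
            return seg.pixel_features(od, enh, resolution=0.46)

        model = seg.fit_pixel_logit(features(train), train.truth_mask, n_sample=30000, seed=0)
        prob = seg.probability_map(model, features(test))
        assert seg.roc_auc(prob, test.truth_mask) >= 0.95
        fibers = seg.segment_fibers(prob, 0.5, 10.0, 0.46)
        planted = len(test.truth_table)
        assert abs(fibers.n_fibers - planted) <= 0.1 * planted
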