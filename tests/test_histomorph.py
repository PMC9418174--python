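"""Pixel classification and percent-positive-area quantification."""

import numpy as np
import pytest

from mrimon.histomorph import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    extract_features,
    iron_load,
    tissue_mask_from_luminance,
    train_pixel_model,
)
from mrimon.pipeline import _annotations_from_truth
from mrimon.synth import generate_stain_image


def _trained_model(frac=0.18, size=150, jitter=0.03, seed=0):
    img, gt = generate_stain_image(size, size, frac, color_jitter_sd=jitter, seed=seed)
    ann = _annotations_from_truth(gt, n_per_class=300, seed=seed + 1)
    return img, gt, train_pixel_model(img, ann, seed=seed + 2)


class TestFeatures:
    def test_constant_image_identical_features(self):
        img = np.full((10, 12, 3), 0.4)
        feats = extract_features(img, scales=(1.0,))
        flat = feats.reshape(-1, feats.shape[-1])
        assert np.allclose(flat, flat[0])

    def test_zero_scales_raw_channels_plus_stain_density(self):
        img = np.random.default_rng(0).uniform(size=(8, 8, 3))
        feats = extract_features(img, scales=())
        assert feats.shape == (8, 8, 5)  # RGB + 2 stain densities
        np.testing.assert_allclose(feats[..., :3], img, rtol=1e-12)

    def test_smoothing_spreads_to_neighbors(self):
        img = np.ones((11, 11, 3))
        img[5, 5] = (0.1, 0.2, 0.5)  # lone blue pixel on white
        feats = extract_features(img, scales=(2.0,))
        # blue channel of the smoothed layer differs from white at a neighbor
        assert feats[5, 7, 5 + 2] != pytest.approx(feats[0, 0, 5 + 2])

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            extract_features(np.ones((4, 4, 3)), scales=(0.0,))


class TestTraining:
    def test_separable_two_color_training_is_perfect(self):
        img, gt, model = _trained_model(jitter=0.0)
        assert model.training_accuracy == 1.0

    def test_single_class_annotations_rejected(self):
        img, _ = generate_stain_image(20, 20, 0.5, seed=0)
        ann = np.zeros((20, 20), np.int32)
        ann[0, :5] = LABEL_POSITIVE
        with pytest.raises(ValueError, match="positive and one negative"):
            train_pixel_model(img, ann)

    def test_heldout_accuracy_on_synthetic_slide(self):
        img, gt, model = _trained_model(jitter=0.04)
        pred = model.predict_positive(img)
        assert (pred == gt).mean() >= 0.95

    def test_annotation_order_permutation_invariance(self):
        img, gt = generate_stain_image(80, 80, 0.2, seed=3)
        ann = _annotations_from_truth(gt, n_per_class=200, seed=4)
        # same labeled set, built in scrambled order
        m1 = train_pixel_model(img, ann, seed=9)
        idx = np.flatnonzero(ann.ravel())
        scrambled = np.zeros_like(ann)
        for i in np.random.default_rng(5).permutation(idx):
            scrambled.ravel()[i] = ann.ravel()[i]
        m2 = train_pixel_model(img, scrambled, seed=9)
        np.testing.assert_array_equal(m1.predict_positive(img), m2.predict_positive(img))

    def test_tiny_training_set_uses_discriminant_fallback(self):
        img, gt = generate_stain_image(30, 30, 0.3, seed=6)
        ann = _annotations_from_truth(gt, n_per_class=10, seed=7)
        model = train_pixel_model(img, ann)
        assert type(model.estimator).__name__ == "LinearDiscriminantAnalysis"


class TestIronLoad:
    def test_recovers_true_fraction_within_one_point(self):
        img, gt, model = _trained_model(frac=0.18)
        res = iron_load(img, model, tissue_mask=np.ones(gt.shape, bool))
        assert res.positive_area_percent == pytest.approx(100 * gt.mean(), abs=1.0)

    def test_all_negative_slide_zero_percent(self):
        img, gt, model = _trained_model()
        neg_img, _ = generate_stain_image(100, 100, 0.0, seed=11)
        res = iron_load(neg_img, model, tissue_mask=np.ones((100, 100), bool))
        assert res.positive_area_percent == 0.0

    def test_pure_positive_region_hundred_percent(self):
        img, gt, model = _trained_model()
        pos_img, _ = generate_stain_image(60, 60, 1.0, seed=12)
        res = iron_load(pos_img, model, tissue_mask=np.ones((60, 60), bool))
        assert res.positive_area_percent == 100.0

    def test_percentage_identity(self):
        img, gt, model = _trained_model(frac=0.25, seed=3)
        res = iron_load(img, model, tissue_mask=np.ones(gt.shape, bool))
        assert res.positive_area_percent == pytest.approx(
            100.0 * res.n_positive / res.n_tissue
        )

    def test_luminance_tissue_mask_excludes_white_background(self):
        img, gt, model = _trained_model(frac=0.2, seed=8)
        framed = np.ones((img.shape[0] + 20, img.shape[1] + 20, 3))  # white border
        framed[10:-10, 10:-10] = img
        mask = tissue_mask_from_luminance(framed)
        assert not mask[:5].any()
        assert mask[10:-10, 10:-10].mean() > 0.95

    def test_empty_tissue_mask_rejected(self):
        img, gt, model = _trained_model()
        with pytest.raises(ValueError, match="empty"):
            iron_load(img, model, tissue_mask=np.zeros(gt.shape, bool))

    def test_monotone_recovery_across_fractions(self):
        estimates = []
        for k, frac in enumerate((0.05, 0.10, 0.20, 0.40)):
            img, gt, model = _trained_model(frac=frac, size=120, seed=20 + k)
            res = iron_load(img, model, tissue_mask=np.ones(gt.shape, bool))
            estimates.append(res.positive_area_percent)
        assert estimates == sorted(estimates)
        assert len(set(estimates)) == 4
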