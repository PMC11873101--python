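"""Integrated gradients: exactness, completeness, smoothing/thresholding."""

import numpy as np
import pytest

from sliceclr import (AttributionMap, integrated_gradients,
                      mean_control_baseline, smooth_threshold)
from sliceclr import _autodiff as ad
from sliceclr._autodiff import Tensor


def linear_scorer(w):
    """F(x) = sum(w * x); gradient is w everywhere."""

    def score(x):
        return float((w * x).sum()), w.copy()

    return score


def tiny_cnn_scorer(rng, h=16, wdt=16):
    """A small differentiable conv scorer built from the engine's ops."""
    pw = Tensor(rng.normal(0, 0.3, (4, 6)), requires_grad=True)
    pb = Tensor(rng.normal(0, 0.1, 6), requires_grad=True)
    fw = Tensor(rng.normal(0, 0.3, (6, 1)), requires_grad=True)

    def score(x):
        xin = Tensor(np.asarray(x)[None, :, :, None], requires_grad=True)
        y = ad.patch_conv(xin, pw, pb, k=2)
        y = ad.gelu(y)
        y = ad.global_avg_pool(y)
        out = ad.mean_all(ad.linear(y, fw))
        out.backward()
        return out.item(), xin.grad[0, :, :, 0].copy()

    return score


class TestMeanBaseline:
    def test_identical_copies_return_that_image(self, rng):
        x = rng.random((8, 8))
        np.testing.assert_allclose(mean_control_baseline([x, x.copy()]), x)

    def test_two_images_average_elementwise(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        np.testing.assert_allclose(mean_control_baseline([a, b]), (a + b) / 2)

    def test_symmetric_pair_cancels(self, rng):
        x = rng.random((5, 5))
        np.testing.assert_allclose(mean_control_baseline([x, -x]),
                                   np.zeros((5, 5)), atol=1e-15)

    def test_shape_mismatch_and_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            mean_control_baseline([])
        with pytest.raises(ValueError):
            mean_control_baseline([rng.random((3, 3)), rng.random((4, 4))])


class TestIntegratedGradients:
    def test_linear_model_is_exact_at_any_step_count(self, rng):
        w = rng.normal(size=(6, 6))
        x, base = rng.random((6, 6)), rng.random((6, 6))
        for n_steps in (1, 5, 50):
            amap = integrated_gradients(linear_scorer(w), x, base,
                                        n_steps=n_steps)
            np.testing.assert_allclose(amap.scores, w * (x - base), atol=1e-12)
            assert amap.completeness_residual < 1e-10

    def test_baseline_equal_to_input_gives_zero_map(self, rng):
        score = tiny_cnn_scorer(rng)
        x = rng.random((16, 16))
        amap = integrated_gradients(score, x, x.copy(), n_steps=10)
        np.testing.assert_allclose(amap.scores, 0.0, atol=1e-15)

    def test_completeness_residual_shrinks_with_more_steps(self, rng):
        """Midpoint-rule residual decreases from 5 to 50 to 500 steps."""
        score = tiny_cnn_scorer(rng)
        x, base = rng.random((16, 16)), rng.random((16, 16)) * 0.2
        residuals = {n: integrated_gradients(score, x, base,
                                             n_steps=n).completeness_residual
                     for n in (5, 50, 500)}
        assert residuals[50] < residuals[5]
        assert residuals[500] < residuals[50]

    def test_attribution_vanishes_where_input_matches_baseline(self, rng):
        """Background pixels shared with the baseline get exactly zero score."""
        score = tiny_cnn_scorer(rng)
        x = rng.random((16, 16))
        base = x.copy()
        inner = np.s_[4:12, 4:12]
        base[inner] = 0.0          # differ only inside the "brain"
        amap = integrated_gradients(score, x, base, n_steps=20)
        outside = np.ones((16, 16), bool)
        outside[inner] = False
        np.testing.assert_allclose(amap.scores[outside], 0.0, atol=1e-15)

    def test_invalid_steps_rejected(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(linear_scorer(np.ones((2, 2))),
                                 np.ones((2, 2)), np.zeros((2, 2)), n_steps=0)


class TestClassMeanAttribution:
    def test_lesion_regions_attract_more_attribution_than_control(
            self, recovery_run):
        """Mean |IG| inside each class's atrophy region exceeds a same-size
        non-discriminative brain region. (In a binary task *both* lesion
        regions are discriminative for both classes, so the control must be
        lesion-free tissue, not the other class's region.)"""
        from sliceclr import class_mean_attribution, mean_control_baseline
        from sliceclr import prepare_slices
        from sliceclr.phantom import BRAIN, DEFAULT_REGIONS, Ellipsoid

        classes = recovery_run["classes"]
        n_keep = recovery_run["n_keep"]
        shape = recovery_run["test_volumes"][0].data.shape
        # same radii as the lesions, planted in lesion-free tissue
        control = Ellipsoid(center=(0.22, 0.5, 0.72), radii=(0.16, 0.10, 0.12))
        control_mask = control.mask(shape) & BRAIN.mask(shape)  # in-brain part
        assert control_mask.sum() > 500
        for region in DEFAULT_REGIONS:
            assert not (control_mask & region.mask(shape)).any()

        window = slice(30, 50)      # coronal indices of the 20-slice window
        control_2d = control_mask[:, window, :].any(axis=1)
        for target in (0, 1):
            donors = [v for v in recovery_run["train_volumes"]
                      if v.label != classes[target]]
            per_index: dict[int, list] = {}
            for v in donors[:5]:
                for rec in prepare_slices(v, n_keep):
                    per_index.setdefault(rec.slice_index, []).append(rec.pixels)
            baselines = [mean_control_baseline(per_index[i])
                         for i in sorted(per_index)]
            targets = [v for v in recovery_run["test_volumes"]
                       if v.label == classes[target]][:7]
            amap = class_mean_attribution(
                recovery_run["extractor"], recovery_run["head"],
                targets, target, classes, n_keep, baselines, n_steps=8)
            lesion_2d = DEFAULT_REGIONS[target].mask(shape)[:, window, :].any(axis=1)
            scores = np.abs(amap.scores)
            assert scores[lesion_2d].mean() > scores[control_2d].mean()

    def test_misclassified_scans_are_excluded(self, recovery_run):
        """A class with no correct classifications yields an error."""
        from sliceclr import class_mean_attribution
        classes = recovery_run["classes"]
        n_keep = recovery_run["n_keep"]
        wrong_only = [v for v in recovery_run["test_volumes"]
                      if v.label == classes[0]][:1]
        with pytest.raises(ValueError, match="no correctly classified"):
            # ask for class-1 maps while supplying only class-0 scans
            class_mean_attribution(
                recovery_run["extractor"], recovery_run["head"], wrong_only,
                1, classes, n_keep,
                [np.zeros((64, 64))] * n_keep, n_steps=2)


class TestSmoothThreshold:
    def _map(self, scores):
        return AttributionMap(scores=scores, baseline_id="b", target_class=0,
                              n_steps=50)

    def test_identity_settings_leave_map_unchanged(self, rng):
        scores = rng.normal(size=(20, 20))
        out = smooth_threshold(self._map(scores), sigma=0.0, keep_quantile=1.0)
        np.testing.assert_array_equal(out.scores, scores)

    def test_keep_quantile_bounds_nonzero_fraction(self, rng):
        scores = rng.normal(size=(50, 50))
        out = smooth_threshold(self._map(scores), sigma=0.0, keep_quantile=0.95)
        assert (out.scores != 0).mean() <= 0.05 + 1 / 50

    def test_constant_map_survives_smoothing(self):
        scores = np.full((10, 10), 0.3)
        out = smooth_threshold(self._map(scores), sigma=2.0, keep_quantile=1.0)
        np.testing.assert_allclose(out.scores, 0.3, atol=1e-12)

    def test_sign_is_preserved(self, rng):
        scores = rng.normal(size=(30, 30))
        out = smooth_threshold(self._map(scores), sigma=1.0, keep_quantile=0.8)
        smoothed_sign = np.sign(out.scores[out.scores != 0])
        assert set(smoothed_sign) <= {-1.0, 1.0}
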