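"""ANN index model: alignment, training, prediction, metrics, combination."""

import numpy as np
import pytest

from doamon import (ANNModel, GoldStandard, MSEMatrix, SampEnParams,
                    align_features_to_target, combine_pre_post, evaluate,
                    predict_index, select_post_scales, train_ann)
from doamon.model import AlignedSamples, split_indices


def make_mse(values, start=0.0, step=5.0, window=30.0, scales=None):
    values = np.atleast_2d(values)
    scales = scales or tuple(range(1, values.shape[1] + 1))
    return MSEMatrix(values, start + step * np.arange(values.shape[0]),
                     scales, SampEnParams(), window, step)


class TestAlignment:
    def test_identical_grids_one_to_one(self, rng):
        vals = rng.random((40, 3))
        mse = make_mse(vals)
        # gold samples at exactly the window end times
        gold = GoldStandard(rng.uniform(0, 100, 40), fs=0.2, t0=30.0)
        out = align_features_to_target(mse, gold)
        assert out.n_dropped == 0
        assert np.array_equal(out.features, vals)

    def test_offset_grid_nearest_window(self, rng):
        vals = rng.random((40, 2))
        mse = make_mse(vals)
        gold = GoldStandard(rng.uniform(0, 100, 38), fs=0.2, t0=32.0)
        out = align_features_to_target(mse, gold)
        assert out.n_dropped == 0
        # exhaustive nearest search oracle
        ends = mse.window_end_s()
        for row, t in zip(out.features, out.times_s):
            assert np.array_equal(row, vals[np.argmin(np.abs(ends - t))])

    def test_disjoint_ranges_error(self, rng):
        mse = make_mse(rng.random((5, 2)))
        gold = GoldStandard(np.full(5, 50.0), fs=0.2, t0=10_000.0)
        with pytest.raises(ValueError):
            align_features_to_target(mse, gold)


class TestSplit:
    def test_disjoint_cover_with_stated_fractions(self):
        train, val, test = split_indices(100, seed=3)
        joined = np.concatenate([train, val, test])
        assert np.array_equal(np.sort(joined), np.arange(100))
        assert abs(len(train) - 70) <= 1
        assert abs(len(val) - 15) <= 1
        assert abs(len(test) - 15) <= 1


class TestTrainANN:
    def _linear_samples(self, rng, n=200, k=4, noise=0.0):
        X = rng.random((n, k))
        w = np.arange(1, k + 1, dtype=float)
        y = 10 + (X @ w) * 8 + noise * rng.standard_normal(n)
        y = np.clip(y, 0, 100)
        return AlignedSamples(X, y, 5.0 * np.arange(n), tuple(range(1, k + 1)))

    def test_learns_noiseless_linear_target(self, rng):
        samples = self._linear_samples(rng)
        model = train_ann(samples, seed=0)
        pred = model.forward(samples.features[model.test_index])
        r = np.corrcoef(pred, samples.target[model.test_index])[0, 1]
        assert r > 0.99

    def test_same_seed_identical_weights(self, rng):
        samples = self._linear_samples(rng, noise=1.0)
        m1 = train_ann(samples, seed=7)
        m2 = train_ann(samples, seed=7)
        for a, b in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)

    def test_nan_rows_dropped(self, rng):
        samples = self._linear_samples(rng, n=60)
        samples.features[5, 0] = np.nan
        model = train_ann(samples, seed=1)
        assert model.n_in == samples.features.shape[1]

    def test_constant_target_rejected(self, rng):
        samples = self._linear_samples(rng)
        samples.target[:] = 42.0
        with pytest.raises(ValueError):
            train_ann(samples)

    def test_too_few_samples(self, rng):
        samples = self._linear_samples(rng, n=10)
        with pytest.raises(ValueError):
            train_ann(samples)


class TestPredict:
    def _model(self, rng, k=3):
        samples = TestTrainANN()._linear_samples(rng, k=k)
        return train_ann(samples, seed=2), samples

    def test_constant_features_constant_output(self, rng):
        model, _ = self._model(rng)
        mse = make_mse(np.tile([0.3, 0.5, 0.7], (6, 1)))
        _, idx = predict_index(model, mse)
        assert np.allclose(idx, idx[0])

    def test_output_clipped_to_0_100(self, rng):
        model, _ = self._model(rng)
        mse = make_mse(rng.uniform(-50, 50, (50, 3)))
        _, idx = predict_index(model, mse)
        assert np.nanmin(idx) >= 0 and np.nanmax(idx) <= 100

    def test_forward_pass_identity_on_training_features(self, rng):
        # serialization round-trip reproduces fitted outputs exactly
        model, samples = self._model(rng)
        restored = ANNModel.from_json(model.to_json())
        assert np.allclose(restored.forward(samples.features),
                           model.forward(samples.features), atol=1e-12)

    def test_scale_mismatch(self, rng):
        model, _ = self._model(rng, k=3)
        with pytest.raises(ValueError):
            predict_index(model, make_mse(rng.random((4, 5))))


class TestEvaluate:
    def test_identity_and_sign_flip(self, rng):
        g = rng.uniform(0, 100, 50)
        assert evaluate(g, g).corr == pytest.approx(1.0)
        assert evaluate(100 - g, g).corr == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        pred = np.array([1.0, 2.0, 4.0, 5.0])
        gold = np.array([10.0, 30.0, 30.0, 50.0])
        # textbook Pearson: cov / (sd_x sd_y)
        expected = np.cov(pred, gold)[0, 1] / (pred.std(ddof=1) * gold.std(ddof=1))
        rep = evaluate(pred, gold)
        assert rep.corr == pytest.approx(expected)
        assert rep.r_squared == pytest.approx(expected ** 2)

    def test_affine_feature_rescaling_invariance(self, rng):
        p, g = rng.random(30), rng.random(30) * 100
        assert evaluate(3 * p + 7, g).corr == pytest.approx(evaluate(p, g).corr)

    def test_zero_variance_undefined(self):
        rep = evaluate(np.full(10, 5.0), np.arange(10.0))
        assert np.isnan(rep.corr)


class TestCombinePrePost:
    def test_selection_rules(self, rng):
        pre = make_mse(rng.random((10, 20)))
        post = make_mse(rng.random((10, 20)))
        assert np.array_equal(combine_pre_post(pre, post, ()).values, pre.values)
        assert np.array_equal(
            combine_pre_post(pre, post, range(1, 21)).values, post.values)
        mixed = combine_pre_post(pre, post, {1, 4, 5})
        for col, s in enumerate(pre.scales):
            src = post if s in {1, 4, 5} else pre
            assert np.array_equal(mixed.values[:, col], src.values[:, col])

    def test_mismatched_grids_rejected(self, rng):
        pre = make_mse(rng.random((10, 4)))
        post = make_mse(rng.random((9, 4)))
        with pytest.raises(ValueError):
            combine_pre_post(pre, post, {1})


class TestSelectPostScales:
    def test_elementwise_comparison(self):
        pre = np.full(20, 0.5)
        post = pre.copy()
        assert select_post_scales(pre, post) == set()
        post[[0, 3, 4]] = 0.9
        assert select_post_scales(pre, post) == {1, 4, 5}
        assert select_post_scales(post, pre) == set()


class TestSummarizeCases:
    def test_cohort_summary(self):
        from doamon import summarize_cases
        corrs = [0.8, 0.9, 0.7]
        rep = summarize_cases(corrs)
        assert rep.corr == pytest.approx(0.8)
        assert rep.cv_pct == pytest.approx(100 * np.std(corrs, ddof=1) / 0.8)
        assert rep.n == 3

    def test_needs_two_cases(self):
        from doamon import summarize_cases
        with pytest.raises(ValueError):
            summarize_cases([0.8])
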