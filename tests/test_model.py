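"""Multi-task CNN: convolution/pooling primitives, loss, gradients."""

import numpy as np
import pytest

import sleepmt as smt
from sleepmt.model import ModelConfig, MultiTaskPosterior, build_model, multitask_loss
from sleepmt.model import conv_over_time, one_max_pool


class TestConvOverTime:
    def test_valid_length(self):
        rng = np.random.default_rng(0)
        out = conv_over_time(rng.standard_normal((2, 4, 29)), rng.standard_normal((2, 4, 3)))
        assert out.shape == (27,)

    def test_full_width_filter_gives_scalar_map(self):
        rng = np.random.default_rng(1)
        out = conv_over_time(rng.standard_normal((1, 3, 29)), rng.standard_normal((1, 3, 29)))
        assert out.shape == (1,)

    def test_template_matching_identity(self):
        """An embedded copy of the filter is the best match, scoring ||filt||_F^2."""
        rng = np.random.default_rng(2)
        filt = rng.standard_normal((2, 3, 4))
        image = np.zeros((2, 3, 12))
        image[:, :, 5:9] = filt
        fmap = conv_over_time(image, filt)
        assert int(np.argmax(fmap)) == 5
        assert fmap[5] == pytest.approx(np.sum(filt**2))

    def test_too_wide_filter_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            conv_over_time(np.zeros((1, 2, 3)), np.zeros((1, 2, 5)))

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        image = rng.standard_normal((2, 4, 10))
        filt = rng.standard_normal((2, 4, 3))
        got = conv_over_time(image, filt)
        expected = np.zeros(8)
        for t in range(8):
            for p in range(2):
                for m in range(4):
                    for dt in range(3):
                        expected[t] += image[p, m, t + dt] * filt[p, m, dt]
        np.testing.assert_allclose(got, expected, atol=1e-6)


class TestOneMaxPool:
    def test_simple_max(self):
        assert one_max_pool([1.0, 3.0, 2.0]) == 3.0

    def test_all_zero_map(self):
        assert one_max_pool(np.zeros(5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            one_max_pool(np.array([]))

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            fm = rng.standard_normal(rng.integers(1, 51))
            best = fm[0]
            for v in fm[1:]:
                if v > best:
                    best = v
            assert one_max_pool(fm) == best


class TestBuildModel:
    def test_pooled_feature_dimension_is_q_times_r(self):
        cfg = ModelConfig(P=1, M=8, T=29, Y=5, Q=100, widths=(3, 5, 7))
        model = build_model(cfg, seed=0)
        assert model._feat_dim == 300
        assert model.params["out_W"].shape == (3 * 5, 300)

    def test_context_three_means_three_rows(self, gen_cfg):
        cfg = ModelConfig(P=1, M=6, T=29, Y=5, tau=1, Q=4)
        model = build_model(cfg, seed=0)
        post = model.forward(np.random.default_rng(0).standard_normal((1, 6, 29)))
        assert post.probs.shape == (3, 5)

    def test_tau0_one_to_many_equals_one_to_one(self):
        """With tau=0 the multi-task model reduces exactly to the standard one."""
        kw = dict(P=2, M=6, T=15, Y=5, tau=0, Q=8, widths=(3, 5))
        m1 = build_model(ModelConfig(scheme="one_to_many", **kw), seed=5)
        m2 = build_model(ModelConfig(scheme="one_to_one", **kw), seed=5)
        assert m1.n_parameters() == m2.n_parameters()
        x = np.random.default_rng(6).standard_normal((4, 2, 6, 15))
        np.testing.assert_array_equal(m1.predict_proba(x), m2.predict_proba(x))

    def test_one_to_one_with_context_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            ModelConfig(scheme="one_to_one", tau=1)

    def test_too_wide_filters_rejected(self):
        with pytest.raises(ValueError, match="widths"):
            ModelConfig(T=5, widths=(3, 5, 7))


class TestForward:
    @pytest.fixture()
    def model(self):
        return build_model(ModelConfig(P=2, M=6, T=15, Y=5, tau=1, Q=6, widths=(3, 5)), seed=1)

    def test_rows_are_distributions(self, model):
        x = np.random.default_rng(7).standard_normal((2, 6, 15))
        post = model.forward(x)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(post.probs >= 0)

    def test_inference_deterministic(self, model):
        x = np.random.default_rng(8).standard_normal((2, 6, 15))
        np.testing.assert_array_equal(model.forward(x).probs, model.forward(x).probs)

    def test_entropy_bounded_by_log_y(self, model):
        x = np.random.default_rng(9).standard_normal((2, 6, 15))
        p = model.forward(x).probs
        ent = -(p * np.log(p)).sum(axis=1)
        assert np.all(ent <= np.log(5) + 1e-12)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="input must be"):
            model.forward(np.zeros((2, 6, 14)))


class TestMultitaskLoss:
    def test_perfect_predictions_zero_loss(self):
        t = np.zeros((4, 3, 5))
        t[:, :, 2] = 1
        assert multitask_loss(np.clip(t, 1e-12, 1), t) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_closed_form(self):
        """Uniform 5-class rows with tau=1: loss per example is 3*ln 5."""
        uni = np.full((7, 3, 5), 0.2)
        t = np.zeros((7, 3, 5))
        t[:, :, 0] = 1
        assert multitask_loss(uni, t) == pytest.approx(3 * np.log(5), rel=1e-12)

    def test_regularizer_isolation(self):
        """With zero cross-entropy, loss is exactly (lambda/2)*||theta||^2."""
        model = build_model(ModelConfig(P=1, M=4, T=10, Y=3, tau=1, Q=2, widths=(3,)), seed=2)
        t = np.zeros((2, 3, 3))
        t[:, :, 1] = 1
        lam = 1e-3
        loss = multitask_loss(t, t, model, lambda_reg=lam)
        direct = sum(np.sum(v**2) for v in model.params.values())
        assert loss == pytest.approx(0.5 * lam * direct, rel=1e-9)

    def test_non_onehot_targets_rejected(self):
        bad = np.full((2, 3, 5), 0.2)
        with pytest.raises(ValueError, match="one-hot"):
            multitask_loss(np.full((2, 3, 5), 0.2), bad)

    def test_batch_order_invariance(self):
        rng = np.random.default_rng(10)
        model = build_model(ModelConfig(P=2, M=5, T=12, Y=4, tau=1, Q=3, widths=(3,)), seed=3)
        X = rng.standard_normal((6, 2, 5, 12))
        codes = rng.integers(0, 4, size=(6, 3))
        t = np.eye(4)[codes]
        l1, _ = model.loss_and_grads(X, t)
        perm = rng.permutation(6)
        l2, _ = model.loss_and_grads(X[perm], t[perm])
        assert l1 == pytest.approx(l2, abs=1e-6)


def _fd_check(model, X, targets, n_coords=40, eps=1e-5, seed=0):
    """Compare analytic gradients to central finite differences."""
    _, grads = model.loss_and_grads(X, targets)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for name, g in grads.items():
        flat = model.params[name].ravel()
        gflat = g.ravel()
        k = min(n_coords, flat.size)
        for i in rng.choice(flat.size, size=k, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = model.loss_and_grads(X, targets)
            flat[i] = orig - eps
            lm, _ = model.loss_and_grads(X, targets)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(gflat[i]), 1e-3)
            worst = max(worst, abs(fd - gflat[i]) / denom)
    return worst


class TestGradients:
    def test_one_max_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(
            P=2, M=3, T=8, Y=3, tau=1, Q=2, widths=(2, 3), dropout=0.0, lambda_reg=1e-3
        )
        model = build_model(cfg, seed=4)
        X = rng.standard_normal((5, 2, 3, 8))
        t = np.eye(3)[rng.integers(0, 3, size=(5, 3))]
        assert _fd_check(model, X, t) < 1e-4

    def test_deep_baseline_gradients_match_finite_differences(self):
        rng = np.random.default_rng(12)
        cfg = ModelConfig(
            P=2, M=4, T=6, Y=3, tau=1, Q=2, arch="deep_baseline",
            dropout=0.0, lambda_reg=0.0,
        )
        model = build_model(cfg, seed=5)
        X = rng.standard_normal((3, 2, 4, 6))
        t = np.eye(3)[rng.integers(0, 3, size=(3, 3))]
        assert _fd_check(model, X, t, n_coords=10) < 1e-4

    def test_dropout_off_at_inference_is_deterministic(self):
        cfg = ModelConfig(P=1, M=4, T=10, Y=3, tau=1, Q=3, widths=(3,), dropout=0.5)
        model = build_model(cfg, seed=6)
        x = np.random.default_rng(13).standard_normal((4, 1, 4, 10))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))


class TestDeepBaseline:
    def test_forward_shape_and_rows(self):
        cfg = ModelConfig(P=3, M=8, T=9, Y=5, tau=1, Q=2, arch="deep_baseline")
        model = build_model(cfg, seed=7)
        x = np.random.default_rng(14).standard_normal((2, 3, 8, 9))
        probs = model.predict_proba(x)
        assert probs.shape == (2, 3, 5)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-6)


class TestMultiTaskPosterior:
    def test_row_accessors(self):
        probs = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        post = MultiTaskPosterior(probs=probs, tau=1)
        np.testing.assert_array_equal(post.classification_row, probs[1])
        np.testing.assert_array_equal(post.row_for_offset(-1), probs[0])
        with pytest.raises(IndexError):
            post.row_for_offset(2)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            MultiTaskPosterior(probs=np.array([[0.5, 0.6]]), tau=0)
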