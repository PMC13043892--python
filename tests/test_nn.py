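"""Network building blocks: gradients, reversal layer, training contracts."""

import math

import numpy as np
import pytest

from sweepdann.nn import (
    ArchitectureSpec,
    ConvBlock,
    GradientReversal,
    TrainConfig,
    build_cnn,
    build_dann,
    cross_entropy,
    grl_lambda,
    load_classifier,
    predict_scores,
    save_classifier,
    train_dann,
    train_source_only,
)


def label_loss(model, x, y):
    feat, _ = model.feature_forward(x)
    logits, _ = model.head_forward(feat, "label")
    return cross_entropy(logits, y)[0]


def label_grads(model, x, y):
    grads = {}
    feat, cache = model.feature_forward(x)
    logits, hcache = model.head_forward(feat, "label")
    _, dlogits = cross_entropy(logits, y)
    dfeat = model.head_backward(dlogits, hcache, "label", grads)
    model.feature_backward(dfeat, cache, grads)
    return grads


class TestGradientReversal:
    def test_forward_is_identity(self, rng):
        v = rng.standard_normal((3, 5))
        assert np.array_equal(GradientReversal(0.7).forward(v), v)

    def test_lambda_zero_kills_gradient(self, rng):
        dy = rng.standard_normal(4)
        assert np.array_equal(GradientReversal(0.0).backward(dy), np.zeros(4))

    def test_scalar_chain_finite_difference(self):
        """f(g(x)) with a reversal between: the numeric gradient of the
        composite equals minus the analytic chain gradient (lambda = 1)."""
        grl = GradientReversal(1.0)

        def g(x):
            return x**3 + 2 * x

        def f(u):
            return math.sin(u)

        x0 = 0.37
        # forward value is unaffected by the reversal layer
        assert f(grl.forward(np.array(g(x0)))) == f(g(x0))
        analytic_chain = math.cos(g(x0)) * (3 * x0**2 + 2)
        # gradient reaching x through the reversal layer
        df_du = math.cos(g(x0))
        dx_through_grl = float(grl.backward(np.array(df_du))) * (3 * x0**2 + 2)
        eps = 1e-7
        numeric = (f(g(x0 + eps)) - f(g(x0 - eps))) / (2 * eps)
        assert abs(numeric - (-dx_through_grl)) / abs(numeric) < 1e-6

    def test_schedule_endpoints(self):
        for gamma in (1.0, 5.0, 10.0):
            assert grl_lambda(0.0, gamma) == 0.0
            assert grl_lambda(1.0, gamma) == pytest.approx(
                2.0 / (1.0 + math.exp(-gamma)) - 1.0
            )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            GradientReversal(-0.1)


class TestBackpropagation:
    def test_full_network_gradients_match_finite_differences(self, toy_spec, rng):
        model = build_cnn(toy_spec, seed=1)
        x = rng.random((4, 10, 32))
        y = np.array([0, 1, 1, 0])
        grads = label_grads(model, x, y)
        for name in sorted(grads):
            p = model.params[name]
            flat_idx = rng.integers(0, p.size, size=min(4, p.size))
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                eps = 1e-6
                old = p[idx]
                p[idx] = old + eps
                lp = label_loss(model, x, y)
                p[idx] = old - eps
                lm = label_loss(model, x, y)
                p[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][idx]) <= 1e-6 * max(1.0, abs(fd)), name


class TestBuild:
    def test_same_seed_same_parameters(self, toy_spec):
        a = build_dann(toy_spec, seed=9)
        b = build_dann(toy_spec, seed=9)
        assert a.params.keys() == b.params.keys()
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_cnn_and_dann_share_label_path_init(self, toy_spec):
        cnn = build_cnn(toy_spec, seed=5)
        dann = build_dann(toy_spec, seed=5)
        for k in cnn.label_path_names():
            assert np.array_equal(cnn.params[k], dann.params[k])
        assert len(cnn.params) < len(dann.params)

    def test_parameter_count_matches_hand_computation(self):
        spec = ArchitectureSpec(
            input_shape=(10, 32),
            blocks=(ConvBlock(4), ConvBlock(8)),
            label_hidden=(16,),
            domain_hidden=(16,),
            feature_pooling="gap",
        )
        # conv: 4*(1*9)+4 + 8*(4*9)+8 = 40 + 296; heads: (16*8+16 + 2*16+2) each
        expected = 40 + 296 + 2 * (16 * 8 + 16 + 2 * 16 + 2)
        assert build_dann(spec, seed=0).n_parameters == expected

    def test_invalid_pool_names_block(self):
        with pytest.raises(ValueError, match="block 1"):
            ArchitectureSpec(
                input_shape=(10, 32),
                blocks=(ConvBlock(4), ConvBlock(8, pool=(3, 2))),
            )

    def test_dann_requires_domain_head(self):
        spec = ArchitectureSpec(input_shape=(10, 32), blocks=(ConvBlock(4),),
                                domain_hidden=None)
        with pytest.raises(ValueError):
            build_dann(spec)


class TestTraining:
    def test_zero_epochs_leaves_parameters_at_init(self, toy_spec, rng):
        model = build_cnn(toy_spec, seed=2)
        before = {k: v.copy() for k, v in model.params.items()}
        x = rng.random((20, 10, 32))
        y = np.array([0, 1] * 10)
        train_source_only(model, x, y, TrainConfig(epochs=0, seed=2))
        for k, v in before.items():
            assert np.array_equal(model.params[k], v)

    def test_separable_toy_problem_reaches_95_percent(self, toy_spec, rng):
        n = 240
        x = rng.random((n, 10, 32)) * 0.2
        y = rng.integers(0, 2, n)
        x[y == 1, :, 10:22] += 0.7  # constant dark band vs none
        model = build_cnn(toy_spec, seed=3)
        train_source_only(model, x[:160], y[:160], TrainConfig(epochs=10, seed=3))
        scores = predict_scores(model, x[160:])
        acc = ((scores > 0.5).astype(int) == y[160:]).mean()
        assert acc >= 0.95

    def test_deterministic_training_reproduces_loss(self, toy_spec, rng):
        x = rng.random((60, 10, 32))
        y = np.array([0, 1] * 30)
        cfg = TrainConfig(epochs=3, seed=8, deterministic=True)
        m1 = train_source_only(build_cnn(toy_spec, seed=8), x, y, cfg)
        m2 = train_source_only(build_cnn(toy_spec, seed=8), x, y, cfg)
        assert m1.history == m2.history

    def test_single_class_rejected(self, toy_spec, rng):
        x = rng.random((10, 10, 32))
        with pytest.raises(ValueError):
            train_source_only(build_cnn(toy_spec, seed=1), x, np.zeros(10, int),
                              TrainConfig(epochs=1))

    def test_empty_target_points_to_source_only(self, toy_spec, rng):
        x = rng.random((10, 10, 32))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="train_source_only"):
            train_dann(build_dann(toy_spec, seed=1), x, np.empty((0, 10, 32)), y,
                       TrainConfig(epochs=1))

    def test_lambda_zero_dann_matches_cnn_label_path(self, toy_spec, rng):
        x = rng.random((64, 10, 32))
        y = np.array([0, 1] * 32)
        xt = rng.random((20, 10, 32))
        cfg = TrainConfig(epochs=2, batch_size=16, seed=4, gamma=0.0)
        cnn = train_source_only(build_cnn(toy_spec, seed=4), x, y, cfg)
        dann = train_dann(build_dann(toy_spec, seed=4), x, xt, y, cfg)
        for k in cnn.label_path_names():
            assert np.array_equal(cnn.params[k], dann.params[k]), k

    def test_dann_reports_domain_diagnostics(self, toy_spec, rng):
        x = rng.random((32, 10, 32))
        y = np.array([0, 1] * 16)
        xt = rng.random((16, 10, 32))
        dann = train_dann(build_dann(toy_spec, seed=4), x, xt, y,
                          TrainConfig(epochs=2, seed=4))
        for epoch in dann.history:
            assert {"label_loss", "domain_loss", "domain_acc"} <= set(epoch)
            assert 0.0 <= epoch["domain_acc"] <= 1.0


class TestScoring:
    def test_probabilities_normalized_and_duplicates_identical(self, toy_spec, rng):
        from sweepdann.nn import softmax

        model = build_cnn(toy_spec, seed=6)
        x = rng.random((5, 10, 32))
        probs = softmax(model.label_logits(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        scores = predict_scores(model, np.vstack([x, x[:1]]))
        assert scores[0] == scores[5]
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_shape_mismatch_rejected(self, toy_spec, rng):
        model = build_cnn(toy_spec, seed=6)
        with pytest.raises(ValueError):
            predict_scores(model, rng.random((3, 10, 16)))

    def test_serialization_round_trip(self, toy_spec, rng, tmp_path):
        x = rng.random((30, 10, 32))
        y = np.array([0, 1] * 15)
        model = train_source_only(build_cnn(toy_spec, seed=7), x, y,
                                  TrainConfig(epochs=2, seed=7))
        path = tmp_path / "model.npz"
        save_classifier(model, path)
        back = load_classifier(path)
        np.testing.assert_allclose(
            predict_scores(model, x), predict_scores(back, x), atol=1e-6
        )
        assert back.kind == "cnn"
        assert back.input_std == model.input_std
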