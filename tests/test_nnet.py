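import math

import numpy as np
import pytest

from mheval.nnet import (
    MLPParams,
    NeuralNetModel,
    TrainConfig,
    backprop_gradients,
    cross_entropy_loss,
    forward,
    init_network,
    lm_step,
    residuals_and_jacobian,
    softmax,
    sse_loss,
    train_gd,
    train_lm,
)
from mheval.synth import GeneratorConfig, generate

XOR_X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
XOR_Y = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 0.0]])


def random_batch(rng, n=8, d=2, k=2):
    X = rng.standard_normal((n, d))
    Y = np.eye(k)[rng.integers(0, k, n)]
    return X, Y


class TestInit:
    def test_deterministic_per_seed(self):
        a = init_network((2, 2, 2), seed=5)
        b = init_network((2, 2, 2), seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_biases_zero_and_param_count(self):
        p = init_network((2, 3, 2), seed=0)
        assert all(np.all(b == 0) for b in p.biases)
        assert p.n_params == 2 * 3 + 3 + 3 * 2 + 2  # = 17
        assert p.to_vector().size == 17

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_network((2, 2), seed=0)
        with pytest.raises(ValueError):
            init_network((2, 0, 2), seed=0)


class TestForward:
    def test_softmax_values_and_stability(self):
        np.testing.assert_allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])
        np.testing.assert_allclose(
            softmax(np.array([1.0, 0.0])), [0.7310585786300049, 0.2689414213699951]
        )
        p = softmax(np.array([1000.0, 0.0]))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            softmax(np.array([]))

    def test_zero_network_is_symmetric(self):
        p = init_network((2, 2, 2), seed=0)
        p.weights = [np.zeros_like(w) for w in p.weights]
        fp = forward(p, np.array([[0.3, -0.7]]))
        np.testing.assert_allclose(fp.activations[1], 0.5)
        np.testing.assert_allclose(fp.probs, 0.5)

    def test_hidden_activations_in_unit_interval_and_batch_consistency(self):
        rng = np.random.default_rng(3)
        p = init_network((4, 5, 3), seed=3)
        X = rng.standard_normal((6, 4))
        fp = forward(p, X)
        assert ((fp.activations[1] > 0) & (fp.activations[1] < 1)).all()
        single = forward(p, X[2])
        np.testing.assert_allclose(single.probs[0], fp.probs[2])

    def test_width_mismatch_rejected(self):
        p = init_network((4, 5, 3), seed=3)
        with pytest.raises(ValueError):
            forward(p, np.zeros((2, 3)))


class TestCrossEntropy:
    def test_uniform_prediction_closed_form(self):
        p = init_network((2, 3, 2), seed=0)
        p.weights = [np.zeros_like(w) for w in p.weights]
        X, Y = random_batch(np.random.default_rng(0), n=6)
        assert cross_entropy_loss(p, X, Y) == pytest.approx(6 * math.log(2), rel=1e-9)

    def test_l2_term_decomposes(self):
        rng = np.random.default_rng(1)
        p = init_network((2, 3, 2), seed=1)
        X, Y = random_batch(rng)
        base = cross_entropy_loss(p, X, Y, lam=0.0)
        reg = cross_entropy_loss(p, X, Y, lam=0.4)
        sq = sum(float(np.sum(w * w)) for w in p.weights)
        assert reg - base == pytest.approx(0.4 / (2 * 8) * sq, rel=1e-9)

    def test_non_one_hot_rejected(self):
        p = init_network((2, 3, 2), seed=1)
        with pytest.raises(ValueError):
            cross_entropy_loss(p, np.zeros((1, 2)), np.array([[0.5, 0.5]]))


class TestGradients:
    def test_backprop_matches_central_differences(self):
        rng = np.random.default_rng(0)
        p = init_network((2, 3, 2), seed=1)
        X, Y = random_batch(rng)
        g = backprop_gradients(p, X, Y, lam=0.1).to_vector()
        x0, eps = p.to_vector(), 1e-6
        num = np.empty_like(x0)
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (
                cross_entropy_loss(p.from_vector(xp), X, Y, 0.1)
                - cross_entropy_loss(p.from_vector(xm), X, Y, 0.1)
            ) / (2 * eps)
        rel = np.abs(g - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() <= 1e-5

    def test_perfect_prediction_gives_zero_output_error(self):
        # drive logits far apart so probs are one-hot to machine precision
        p = init_network((1, 2, 2), seed=0)
        p.weights[-1] = np.array([[50.0, -50.0], [50.0, -50.0]])
        X = np.array([[1.0]])
        Y = np.array([[1.0, 0.0]])
        fp = forward(p, X)
        np.testing.assert_allclose(fp.probs - Y, 0.0, atol=1e-12)

    def test_jacobian_matches_central_differences(self):
        rng = np.random.default_rng(4)
        p = init_network((2, 3, 2), seed=7)
        X, Y = random_batch(rng)
        e, J = residuals_and_jacobian(p, X, Y)
        x0, eps = p.to_vector(), 1e-6
        for i in range(0, x0.size, 3):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            ep = (Y - forward(p.from_vector(xp), X).sigmoid_out).ravel()
            em = (Y - forward(p.from_vector(xm), X).sigmoid_out).ravel()
            np.testing.assert_allclose(J[:, i], (ep - em) / (2 * eps), atol=1e-7)


class TestGradientDescent:
    def test_xor_loss_decreases(self):
        p = init_network((2, 2, 2), seed=3)
        cfg = TrainConfig(
            objective="cross_entropy_gd", learning_rate=0.5, max_iters=500, tol=0.0, seed=3
        )
        _, trace = train_gd(p, XOR_X, XOR_Y, cfg)
        assert trace[-1] < trace[0]

    def test_zero_learning_rate_is_a_null_step(self):
        p = init_network((2, 2, 2), seed=3)
        cfg = TrainConfig(
            objective="cross_entropy_gd", learning_rate=0.0, max_iters=3, tol=-1.0, seed=3
        )
        out, _ = train_gd(p, XOR_X, XOR_Y, cfg)
        np.testing.assert_array_equal(out.to_vector(), p.to_vector())

    def test_same_seed_same_trace(self):
        cfg = TrainConfig(
            objective="cross_entropy_gd", learning_rate=0.5, max_iters=50, tol=0.0, seed=9
        )
        t1 = train_gd(init_network((2, 2, 2), 9), XOR_X, XOR_Y, cfg)[1]
        t2 = train_gd(init_network((2, 2, 2), 9), XOR_X, XOR_Y, cfg)[1]
        assert t1 == t2

    def test_wrong_objective_rejected(self):
        with pytest.raises(ValueError):
            train_gd(
                init_network((2, 2, 2), 0),
                XOR_X,
                XOR_Y,
                TrainConfig(objective="sse_lm"),
            )


class TestSSE:
    def test_values_and_additivity(self):
        p = init_network((2, 2, 2), seed=0)
        assert sse_loss(p, XOR_X, XOR_Y) == pytest.approx(
            sse_loss(p, XOR_X[:2], XOR_Y[:2]) + sse_loss(p, XOR_X[2:], XOR_Y[2:])
        )

    def test_half_residual_value(self):
        # single output unit at exactly 0.5 with target 1 contributes 0.125
        p = MLPParams(
            weights=[np.zeros((1, 1)), np.zeros((1, 1))],
            biases=[np.zeros(1), np.zeros(1)],
        )
        X = np.array([[0.0]])
        D = np.array([[1.0]])
        assert sse_loss(p, X, D) == pytest.approx(0.125)


class TestLevenbergMarquardt:
    def test_gauss_newton_step_exact_for_linear_residuals(self):
        # model y = w·x on y = 2x data: J is constant, one undamped step from
        # any start lands on the least-squares optimum
        x = np.array([1.0, 2.0, 3.0])
        d = 2.0 * x
        w0 = -0.7
        e = d - w0 * x
        J = (-x)[:, None]
        delta = lm_step(J, e, mu=0.0)
        assert w0 + delta[0] == pytest.approx(2.0, abs=1e-12)

    def test_large_mu_step_points_along_negative_gradient(self):
        rng = np.random.default_rng(2)
        p = init_network((2, 3, 2), seed=2)
        X, Y = random_batch(rng)
        e, J = residuals_and_jacobian(p, X, Y)
        delta = lm_step(J, e, mu=1e12)
        g = -(J.T @ e)
        cos = float(delta @ g / (np.linalg.norm(delta) * np.linalg.norm(g)))
        assert cos >= 0.999
        assert delta.size == p.n_params

    def test_accepted_trace_strictly_decreasing_on_xor(self):
        p = init_network((2, 2, 2), seed=1)
        cfg = TrainConfig(objective="sse_lm", max_iters=60, tol=0.0, seed=1)
        _, trace, info = train_lm(p, XOR_X, XOR_Y, cfg)
        assert all(b < a for a, b in zip(trace, trace[1:]))
        assert info["n_iterations"] == len(trace) - 1

    def test_xor_reaches_low_sse_on_most_seeds(self):
        # a minority of starts land in the well-known XOR local minima; the
        # healthy majority should drive the SSE below 0.01
        hits = 0
        for s in range(10):
            p = init_network((2, 2, 2), seed=s)
            cfg = TrainConfig(objective="sse_lm", max_iters=200, tol=0.0, seed=s)
            _, trace, _ = train_lm(p, XOR_X, XOR_Y, cfg)
            hits += trace[-1] < 0.01
        assert hits >= 7

    def test_zero_residual_start_converges_immediately(self):
        p = init_network((2, 2, 2), seed=0)
        e, J = residuals_and_jacobian(p, XOR_X, XOR_Y)
        # build a problem whose residuals are already zero: target = output
        D = forward(p, XOR_X).sigmoid_out
        # targets must be one-hot for sse_loss; emulate via direct API instead
        delta = lm_step(J, np.zeros_like(e), mu=1e-3)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_determinism(self):
        cfg = TrainConfig(objective="sse_lm", max_iters=30, tol=0.0, seed=4)
        t1 = train_lm(init_network((2, 2, 2), 4), XOR_X, XOR_Y, cfg)[1]
        t2 = train_lm(init_network((2, 2, 2), 4), XOR_X, XOR_Y, cfg)[1]
        assert t1 == t2


class TestModelWrapper:
    def test_fit_predict_on_synthetic_data(self):
        data = generate(GeneratorConfig(n_samples=200, separation=4.0, label_noise=0.0, seed=6))
        cfg = TrainConfig(objective="sse_lm", max_iters=25, seed=6)
        res = NeuralNetModel(data, (6,), cfg).fit()
        proba = res.predict_proba(data)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert float(np.mean(res.predict(data) == data.labels)) > 0.8
        assert "Neural Network Results" in res.summary()

    def test_validation_selection_records_best_accuracy(self):
        data = generate(GeneratorConfig(n_samples=300, separation=3.0, seed=8))
        cfg = TrainConfig(objective="sse_lm", max_iters=15, seed=8, validation_fraction=0.2)
        res = NeuralNetModel(data, (6,), cfg).fit()
        assert 0.0 <= res.info["best_validation_accuracy"] <= 1.0
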