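"""Regressor tests: LS-SVM algebra, PSO behaviour, network gradients."""

import math

import numpy as np
import pytest

import fishcut as fc
from fishcut.models import (LSSVM_GAM_RANGE, LSSVM_SIG2_RANGE, PSOConfig,
                            _gram, bp_forward, bp_loss_and_grad, bp_train,
                            lssvm_fit, lssvm_predict, lstm_forward,
                            lstm_loss_and_grad, new_bp_network, new_lstm,
                            pso_bp_fit, pso_optimize, rbf_kernel,
                            train_regressor, tune_lssvm)


def central_diff_grad(loss, theta, eps=1e-5):
    g = np.zeros_like(theta)
    for j in range(theta.size):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        g[j] = (loss(tp) - loss(tm)) / (2 * eps)
    return g


def max_rel_dev(a, b):
    return float(np.max(np.abs(a - b) / np.maximum(1e-8, np.abs(a) + np.abs(b))))


class TestRBFKernel:
    def test_zero_distance_is_one(self):
        u = np.array([1.0, -2.0, 0.5])
        assert rbf_kernel(u, u, sig2=3.0) == 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=3), rng.normal(size=3)
        k = rbf_kernel(u, v, sig2=2.0)
        assert k == rbf_kernel(v, u, sig2=2.0)
        assert 0 < k <= 1

    def test_closed_form(self):
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])  # squared distance 2
        assert rbf_kernel(u, v, sig2=1.0) == pytest.approx(math.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(fc.InvalidArgumentError):
            rbf_kernel(np.ones(2), np.ones(3), 1.0)


class TestLSSVM:
    def test_single_point_closed_form(self):
        model = lssvm_fit(np.array([[1.0, 2.0]]), np.array([54.3]), 1.0, 1.0)
        assert model.bias == pytest.approx(54.3)
        assert model.alphas[0] == pytest.approx(0.0, abs=1e-12)
        pred = lssvm_predict(model, np.array([[9.0, -4.0]]))
        assert pred[0] == pytest.approx(54.3)

    def test_alphas_sum_to_zero(self):
        rng = np.random.default_rng(2)
        model = lssvm_fit(rng.normal(size=(12, 3)), rng.normal(size=12), 5.0, 2.0)
        assert abs(model.alphas.sum()) < 1e-8

    def test_matches_explicit_elimination_oracle(self):
        """Solve the bordered system by hand-rolled Gaussian elimination
        with partial pivoting and compare alphas and bias."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        gam, sig2 = 3.0, 1.7
        model = lssvm_fit(X, y, gam, sig2)

        A = np.zeros((9, 9))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = _gram(X, X, sig2) + np.eye(8) / gam
        b = np.concatenate([[0.0], y])
        M = np.column_stack([A, b])
        for col in range(9):
            piv = col + int(np.argmax(np.abs(M[col:, col])))
            M[[col, piv]] = M[[piv, col]]
            M[col] /= M[col, col]
            for row in range(9):
                if row != col:
                    M[row] -= M[row, col] * M[col]
        sol = M[:, -1]
        assert model.bias == pytest.approx(sol[0], abs=1e-9)
        np.testing.assert_allclose(model.alphas, sol[1:], atol=1e-9)

    def test_dual_system_residual_small(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = lssvm_fit(X, y, 10.0, 1.0)
        A = np.zeros((21, 21))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = _gram(X, X, 1.0) + np.eye(20) / 10.0
        res = A @ np.concatenate([[model.bias], model.alphas]) - np.concatenate([[0.0], y])
        assert np.abs(res).max() / max(1.0, np.abs(y).max()) < 1e-8

    def test_interpolates_as_regularization_vanishes(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        model = lssvm_fit(X, y, gam=1e8, sig2=1.0)
        assert np.abs(lssvm_predict(model, X) - y).max() < 1e-3

    def test_prediction_is_kernel_sum(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 2))
        y = rng.normal(size=7)
        model = lssvm_fit(X, y, 2.0, 0.8)
        q = rng.normal(size=(3, 2))
        manual = np.array([
            sum(model.alphas[i] * rbf_kernel(qq, X[i], 0.8) for i in range(7))
            + model.bias
            for qq in q
        ])
        np.testing.assert_allclose(lssvm_predict(model, q), manual, atol=1e-12)


class TestPSO:
    def test_sphere_reaches_near_zero(self):
        cfg = PSOConfig(position_bounds=((-2, 2), (-2, 2)),
                        velocity_bounds=((-1, 1), (-1, 1)), seed=0)
        _, best, _ = pso_optimize(lambda x: float(np.sum(x * x)), cfg)
        assert best < 1e-4

    def test_history_non_increasing_and_deterministic(self):
        cfg = PSOConfig(position_bounds=((-2, 2), (-2, 2)),
                        velocity_bounds=((-1, 1), (-1, 1)), max_iter=50, seed=3)
        obj = lambda x: float(np.sum((x - 0.5) ** 2))
        _, _, h1 = pso_optimize(obj, cfg)
        _, _, h2 = pso_optimize(obj, cfg)
        assert np.all(np.diff(h1) <= 0)
        np.testing.assert_array_equal(h1, h2)
        assert h1.size == 51

    def test_positions_stay_in_bounds(self):
        seen = []

        def objective(x):
            seen.append(x.copy())
            return float(np.sum(x * x))

        cfg = PSOConfig(position_bounds=((-2, 2), (-1, 3)),
                        velocity_bounds=((-1, 1), (-1, 1)), max_iter=30, seed=4)
        pso_optimize(objective, cfg)
        seen = np.array(seen)
        assert seen[:, 0].min() >= -2 and seen[:, 0].max() <= 2
        assert seen[:, 1].min() >= -1 and seen[:, 1].max() <= 3


@pytest.fixture(scope="module")
def smooth_problem():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + X[:, 2]
    return X, y


class TestTuneLSSVM:

    def test_optimum_beats_box_corners(self, smooth_problem):
        X, y = smooth_problem
        cfg = PSOConfig(max_iter=15, seed=1)
        model, history = tune_lssvm(X, y, cfg)

        def cv_rmse(gam, sig2, seed=1, k=5):
            n = y.size
            folds = [np.random.default_rng(seed).permutation(n)[i::k]
                     for i in range(k)]
            sse = 0.0
            for test in folds:
                train = np.setdiff1d(np.arange(n), test)
                m = lssvm_fit(X[train], y[train], gam, sig2)
                sse += float(np.sum((lssvm_predict(m, X[test]) - y[test]) ** 2))
            return math.sqrt(sse / n)

        best = history[-1]
        for gam in LSSVM_GAM_RANGE:
            for sig2 in LSSVM_SIG2_RANGE:
                assert best <= cv_rmse(gam, sig2) + 1e-9

    def test_fitness_plateaus(self, smooth_problem):
        X, y = smooth_problem
        _, history = tune_lssvm(X, y, PSOConfig(max_iter=40, seed=2))
        # the running best stops improving well before the end
        tail = history[-10:]
        assert tail.max() - tail.min() < 1e-6

    def test_deterministic(self, smooth_problem):
        X, y = smooth_problem
        cfg = PSOConfig(max_iter=10, seed=5)
        m1, _ = tune_lssvm(X, y, cfg)
        m2, _ = tune_lssvm(X, y, cfg)
        assert (m1.gam, m1.sig2) == (m2.gam, m2.sig2)

    def test_needs_enough_samples(self):
        with pytest.raises(fc.InvalidArgumentError):
            tune_lssvm(np.ones((3, 2)), np.ones(3))


class TestBPNetwork:
    def test_zero_network_predicts_zero(self):
        net = new_bp_network(3, 10, seed=0)
        zero = net.with_parameters(np.zeros(net.n_parameters()))
        np.testing.assert_array_equal(bp_forward(zero, np.ones((4, 3))), 0.0)

    def test_hand_computed_forward_pass(self):
        net = new_bp_network(2, 2, seed=0).with_parameters(
            np.array([0.5, -1.0, 1.0, 0.0,   # W1 (2x2, row-major)
                      0.1, -0.2,             # b1
                      2.0, -3.0,             # w2
                      0.25]))                # b2
        x = np.array([[1.0, 2.0]])
        a1 = 1 / (1 + math.exp(-(0.5 * 1 + 1.0 * 2 + 0.1)))
        a2 = 1 / (1 + math.exp(-(-1.0 * 1 + 0.0 * 2 - 0.2)))
        expected = 2.0 * a1 - 3.0 * a2 + 0.25
        assert bp_forward(net, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        net = new_bp_network(3, 10, seed=1)
        worst = 0.0
        for k in range(5):
            theta = net.flatten() + rng.normal(0, 0.3, net.n_parameters())
            _, g = bp_loss_and_grad(net.with_parameters(theta), X, y)
            gn = central_diff_grad(
                lambda th: bp_loss_and_grad(net.with_parameters(th), X, y)[0],
                theta)
            worst = max(worst, max_rel_dev(g, gn))
        assert worst < 1e-5

    def test_fits_linear_map(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([0.4, -0.3, 0.2]) + 0.1
        net = new_bp_network(3, 10, seed=2, learning_rate=0.5, max_iter=5000)
        trained = bp_train(net, X, y)
        loss, _ = bp_loss_and_grad(trained, X, y)
        assert loss <= 1e-3

    def test_goal_met_at_init_returns_unchanged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 3))
        net = new_bp_network(3, 10, seed=3)
        y = bp_forward(net, X)  # zero loss at initialization
        trained = bp_train(net, X, y)
        np.testing.assert_array_equal(trained.flatten(), net.flatten())

    def test_divergence_detected(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 3)) * 5
        y = rng.normal(size=10) * 100
        net = new_bp_network(3, 10, seed=4, learning_rate=1e6, max_iter=200)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(fc.TrainingDivergedError):
                bp_train(net, X, y, keep_best=False)


class TestPSOBP:
    def test_refinement_never_worse_than_pso(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        y = np.tanh(X[:, 0]) + 0.3 * X[:, 1]
        pso = PSOConfig(max_iter=30, seed=6)
        raw = pso_bp_fit(X, y, pso, {"seed": 6}, refine=False)
        refined = pso_bp_fit(X, y, pso, {"seed": 6}, refine=True)
        assert bp_loss_and_grad(refined, X, y)[0] <= \
            bp_loss_and_grad(raw, X, y)[0] + 1e-12

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        pso = PSOConfig(max_iter=10, seed=7)
        a = pso_bp_fit(X, y, pso, {"seed": 7})
        b = pso_bp_fit(X, y, pso, {"seed": 7})
        np.testing.assert_array_equal(a.flatten(), b.flatten())


class TestLSTM:
    def test_zero_parameters_output_bias(self):
        model = new_lstm(hidden_size=4, seed=0)
        zero = model.with_parameters(np.zeros(model.flatten().size))
        out = lstm_forward(zero, np.array([[0.3, -0.7, 1.1]]))
        assert out[0] == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_single_unit_recurrence(self):
        model = new_lstm(hidden_size=1, seed=0)
        # W_f, V_f, b_f, W_i, V_i, b_i, W_o, V_o, b_o, W_g, V_g, b_g, dense, bias
        theta = np.array([0.5, 0.1, 0.0,
                          -0.4, 0.2, 0.1,
                          0.3, -0.1, 0.2,
                          0.8, 0.05, -0.1,
                          1.5, 0.25])
        model = model.with_parameters(theta)
        x = [0.2, -0.5, 0.9]
        sig = lambda a: 1 / (1 + math.exp(-a))
        h = c = 0.0
        for xt in x:
            f = sig(0.5 * xt + 0.1 * h + 0.0)
            i = sig(-0.4 * xt + 0.2 * h + 0.1)
            o = sig(0.3 * xt - 0.1 * h + 0.2)
            g = math.tanh(0.8 * xt + 0.05 * h - 0.1)
            c = f * c + i * g
            h = o * math.tanh(c)
        expected = 1.5 * h + 0.25
        got = lstm_forward(model, np.array([x]))
        assert got[0] == pytest.approx(expected, abs=1e-12)

    def test_hidden_state_bounded(self):
        model = new_lstm(hidden_size=8, seed=1)
        from fishcut.models import _lstm_pass
        h, caches = _lstm_pass(model, np.random.default_rng(2).normal(size=(20, 3)))
        assert np.all(np.abs(h) < 1.0)
        for cc in caches:
            assert np.all((cc["f"] > 0) & (cc["f"] < 1))
            assert np.all(np.abs(cc["tc"]) < 1)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        model = new_lstm(hidden_size=4, seed=2)
        worst = 0.0
        for k in range(3):
            theta = model.flatten() + rng.normal(0, 0.2, model.flatten().size)
            _, g = lstm_loss_and_grad(model.with_parameters(theta), X, y)
            gn = central_diff_grad(
                lambda th: lstm_loss_and_grad(model.with_parameters(th), X, y)[0],
                theta)
            worst = max(worst, max_rel_dev(g, gn))
        assert worst < 1e-4

    def test_training_loss_declines(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 3))
        y = 0.7 * X[:, 0] - 0.4 * X[:, 1] + 0.2 * np.tanh(X[:, 2])
        model, hist = fc.lstm_fit(X, y, hidden_size=8, seed=3)
        loss = hist["train_loss"]

        def smooth(v, w=10):
            return np.convolve(v, np.ones(w) / w, mode="valid")

        s = smooth(loss)
        assert s[-1] < s[10]

    def test_deterministic(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        a, _ = fc.lstm_fit(X, y, hidden_size=4, max_iter=20, seed=4)
        b, _ = fc.lstm_fit(X, y, hidden_size=4, max_iter=20, seed=4)
        np.testing.assert_array_equal(a.flatten(), b.flatten())

    def test_non_finite_parameters_rejected(self):
        model = new_lstm(hidden_size=2, seed=0)
        theta = model.flatten()
        theta[0] = np.inf
        with pytest.raises(fc.InvalidArgumentError):
            lstm_forward(model.with_parameters(theta), np.ones((1, 3)))


class TestTrainedRegressor:
    def test_lssvm_shift_equivariance(self, small_noisy_scores):
        """Adding a constant to the targets shifts predictions by exactly
        that constant (the bias and target scaling absorb shifts)."""
        S, y = small_noisy_scores
        a = train_regressor("lssvm", S, y, seed=1, gam=10.0, sig2=3.0)
        b = train_regressor("lssvm", S, y + 7.0, seed=1, gam=10.0, sig2=3.0)
        np.testing.assert_allclose(b.predict(S), a.predict(S) + 7.0, atol=1e-8)

    def test_network_shift_equivariance_same_seed(self, small_noisy_scores):
        S, y = small_noisy_scores
        kw = dict(hidden_size=4, max_iter=30)
        a = train_regressor("lstm", S, y, seed=2, **kw)
        b = train_regressor("lstm", S, y + 5.0, seed=2, **kw)
        np.testing.assert_allclose(b.predict(S), a.predict(S) + 5.0, atol=1e-6)

    def test_predictions_finite_and_in_mm(self, small_noisy_scores):
        S, y = small_noisy_scores
        reg = train_regressor("psobp", S, y, seed=3,
                              pso_config=PSOConfig(max_iter=20, seed=3))
        pred = reg.predict(S)
        assert np.all(np.isfinite(pred))
        assert 30 < pred.mean() < 80  # plausible head lengths in mm

    def test_unknown_kind_rejected(self):
        with pytest.raises(fc.InvalidArgumentError):
            train_regressor("mpr", np.ones((5, 3)), np.ones(5))
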