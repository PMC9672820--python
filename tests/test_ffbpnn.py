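import copy
import itertools

import numpy as np
import pytest

from memdbci import ffbpnn as nn
from memdbci.exceptions import InvalidSpecError


class TestTransferFunctions:
    def test_values_at_zero_and_linearity(self):
        assert nn.transfer("tansig", 0.0) == 0.0
        assert nn.transfer("logsig", 0.0) == 0.5
        assert nn.transfer("purelin", 3.7) == 3.7

    def test_derivatives_at_zero(self):
        assert nn.transfer_deriv("tansig", 0.0) == 1.0
        assert nn.transfer_deriv("logsig", 0.0) == 0.25
        assert nn.transfer_deriv("purelin", -2.0) == 1.0

    @pytest.mark.parametrize("tag", nn.TRANSFER_FUNCTIONS)
    def test_derivative_matches_finite_difference(self, tag, rng):
        v = rng.uniform(-3, 3, size=20)
        eps = 1e-6
        fd = (nn.transfer(tag, v + eps) - nn.transfer(tag, v - eps)) / (2 * eps)
        np.testing.assert_allclose(nn.transfer_deriv(tag, v), fd, atol=1e-8)

    def test_unknown_tag_rejected(self):
        with pytest.raises(InvalidSpecError):
            nn.transfer("relu", 0.0)


def assemble_gradient(params, x, t):
    acts, pre = nn.forward(params, x)
    s = nn.sensitivities(params, acts, pre, t)
    gW = [np.outer(s[k], acts[k]) for k in range(params.n_layers)]
    gb = [s[k] for k in range(params.n_layers)]
    return gW, gb


def fd_gradient(params, x, t, eps=1e-6):
    def loss(p):
        a, _ = nn.forward(p, x)
        return float(np.sum((np.asarray(t) - a[-1]) ** 2))

    gW, gb = [], []
    for k in range(params.n_layers):
        g = np.zeros_like(params.W[k])
        for i, j in np.ndindex(g.shape):
            q = copy.deepcopy(params)
            q.W[k][i, j] += eps
            up = loss(q)
            q.W[k][i, j] -= 2 * eps
            g[i, j] = (up - loss(q)) / (2 * eps)
        gW.append(g)
        g = np.zeros_like(params.b[k])
        for i in range(g.size):
            q = copy.deepcopy(params)
            q.b[k][i] += eps
            up = loss(q)
            q.b[k][i] -= 2 * eps
            g[i] = (up - loss(q)) / (2 * eps)
        gb.append(g)
    return gW, gb


class TestForward:
    def test_identity_purelin_layer(self):
        p = nn.NetParams([3, 3], [np.eye(3)], [np.zeros(3)], ["purelin"])
        acts, _ = nn.forward(p, np.array([1.0, -2.0, 3.0]))
        np.testing.assert_array_equal(acts[-1], [1.0, -2.0, 3.0])

    def test_zero_weights_tansig_outputs_zero(self):
        p = nn.NetParams([2, 4], [np.zeros((4, 2))], [np.zeros(4)], ["tansig"])
        acts, _ = nn.forward(p, np.array([5.0, -5.0]))
        np.testing.assert_array_equal(acts[-1], np.zeros(4))

    def test_hand_computed_2_2_1(self):
        W1 = np.array([[0.5, -0.25], [1.0, 2.0]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.5, -0.5]])
        b2 = np.array([0.05])
        p = nn.NetParams([2, 2, 1], [W1, W2], [b1, b2], ["tansig", "purelin"])
        x = np.array([0.3, -0.7])
        h = np.tanh(W1 @ x + b1)
        expected = W2 @ h + b2
        acts, _ = nn.forward(p, x)
        np.testing.assert_allclose(acts[-1], expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        p = nn.init_params([3, 2], "tansig", seed=0)
        with pytest.raises(InvalidSpecError):
            nn.forward(p, np.zeros(5))


class TestSensitivities:
    def test_perfect_output_zero_sensitivities(self):
        p = nn.init_params([2, 3, 2], "tansig", seed=0)
        acts, pre = nn.forward(p, np.array([0.1, 0.2]))
        s = nn.sensitivities(p, acts, pre, acts[-1])
        assert all(np.all(sk == 0) for sk in s)

    def test_single_purelin_unit_output_rule(self):
        p = nn.NetParams([1, 1], [np.array([[1.0]])], [np.array([0.0])], ["purelin"])
        acts, pre = nn.forward(p, np.array([2.0]))
        s = nn.sensitivities(p, acts, pre, np.array([5.0]))
        d = 5.0 - acts[-1][0]
        np.testing.assert_allclose(s[-1], [-2.0 * d])

    @pytest.mark.parametrize("sizes", [[1, 1, 1], [3, 4, 2], [5, 10, 4]])
    @pytest.mark.parametrize(
        "tfs", list(itertools.product(nn.TRANSFER_FUNCTIONS, repeat=2))
    )
    def test_gradient_matches_finite_differences(self, sizes, tfs, rng):
        p = nn.init_params(sizes, list(tfs), seed=11)
        x = rng.uniform(-1, 1, size=sizes[0])
        t = rng.uniform(-1, 1, size=sizes[-1])
        gW, gb = assemble_gradient(p, x, t)
        fW, fb = fd_gradient(p, x, t)
        for a, b in zip(gW + gb, fW + fb):
            np.testing.assert_allclose(a, b, rtol=1e-5, atol=1e-7)


class TestUpdate:
    def test_zero_sensitivities_no_change(self):
        p = nn.init_params([2, 3, 1], "tansig", seed=0)
        acts, pre = nn.forward(p, np.array([0.5, -0.5]))
        s = nn.sensitivities(p, acts, pre, acts[-1])
        q = nn.update(p, s, acts, alpha=0.1)
        for a, b in zip(p.W + p.b, q.W + q.b):
            np.testing.assert_array_equal(a, b)

    def test_zero_alpha_no_change(self, rng):
        p = nn.init_params([2, 2], "purelin", seed=0)
        acts, pre = nn.forward(p, rng.normal(size=2))
        s = nn.sensitivities(p, acts, pre, rng.normal(size=2))
        q = nn.update(p, s, acts, alpha=0.0)
        np.testing.assert_array_equal(p.W[0], q.W[0])

    def test_reduces_to_lms_for_single_linear_unit(self):
        # one linear unit: the step is w <- w + 2*alpha*e*input, the
        # Widrow-Hoff rule
        w0, alpha = 0.3, 0.05
        p = nn.NetParams([1, 1], [np.array([[w0]])], [np.array([0.0])], ["purelin"])
        x, t = np.array([1.7]), np.array([2.0])
        acts, pre = nn.forward(p, x)
        e = t[0] - acts[-1][0]
        s = nn.sensitivities(p, acts, pre, t)
        q = nn.update(p, s, acts, alpha)
        assert q.W[0][0, 0] == pytest.approx(w0 + 2 * alpha * e * x[0])

    def test_update_is_pure(self):
        p = nn.init_params([2, 2], "tansig", seed=0)
        before = copy.deepcopy(p)
        acts, pre = nn.forward(p, np.ones(2))
        s = nn.sensitivities(p, acts, pre, np.zeros(2))
        nn.update(p, s, acts, 0.1)
        np.testing.assert_array_equal(p.W[0], before.W[0])


XOR_X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
XOR_T = np.array([[-1], [1], [1], [-1]], float)


class TestTrain:
    def test_xor_reaches_goal(self):
        cfg = nn.TrainConfig(alpha=0.1, error_goal=1e-2, max_epochs=5000, seed=3)
        r = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg, tf="tansig")
        assert r.stopped_by == "goal"
        assert r.epochs_run <= 5000
        assert r.mse_history[-1] <= 1e-2

    def test_mse_trend_downward_on_xor(self):
        cfg = nn.TrainConfig(alpha=0.1, error_goal=1e-9, max_epochs=500, seed=3)
        r = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg, tf="tansig")
        assert r.mse_history[-1] < r.mse_history[0]

    def test_separable_blobs_high_accuracy(self, rng):
        n = 60
        X = np.vstack([rng.normal(-2, 0.5, (n, 2)), rng.normal(2, 0.5, (n, 2))])
        y = np.repeat([0, 1], n)
        T = nn.one_hot(y, 2)
        cfg = nn.TrainConfig(alpha=0.01, error_goal=1e-2, max_epochs=2000, seed=0)
        r = nn.train(X[::2], T[::2], [2, 10, 2], cfg)
        acc = np.mean(nn.classify(r.params, X[1::2]) == y[1::2])
        assert acc >= 0.98

    def test_huge_goal_stops_after_one_epoch(self):
        cfg = nn.TrainConfig(alpha=0.1, error_goal=1e9, max_epochs=100, seed=0)
        r = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg)
        assert r.stopped_by == "goal" and r.epochs_run == 1

    def test_seed_determinism(self):
        cfg = nn.TrainConfig(alpha=0.1, error_goal=1e-3, max_epochs=200, seed=9)
        a = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg)
        b = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg)
        assert a.mse_history == b.mse_history
        for wa, wb in zip(a.params.W, b.params.W):
            np.testing.assert_array_equal(wa, wb)

    def test_online_mode_also_learns_xor(self):
        cfg = nn.TrainConfig(alpha=0.02, error_goal=1e-2, max_epochs=5000, seed=0,
                             mode="online")
        r = nn.train(XOR_X, XOR_T, [2, 4, 1], cfg)
        assert r.stopped_by == "goal"


class TestClassify:
    def test_argmax_and_tie_rule(self):
        p = nn.NetParams([4, 4], [np.eye(4)], [np.zeros(4)], ["purelin"])
        assert nn.classify(p, np.array([[0.9, -0.2, 0.1, -0.8]]))[0] == 0
        p2 = nn.NetParams([2, 2], [np.eye(2)], [np.zeros(2)], ["purelin"])
        assert nn.classify(p2, np.array([[0.5, 0.5]]))[0] == 0

    def test_one_hot_round_trip(self):
        labels = np.array([2, 0, 3, 1, 1])
        T = nn.one_hot(labels, 4)
        p = nn.NetParams([4, 4], [np.eye(4)], [np.zeros(4)], ["purelin"])
        np.testing.assert_array_equal(nn.classify(p, T), labels)
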