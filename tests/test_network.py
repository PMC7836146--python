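"""Hybrid network: gate equations, forward composition, gradients, training."""

import math

import numpy as np
import pytest

from natalweight import network as nt


def _zero_layer(hidden=2, inp=1):
    z = lambda *s: np.zeros(s)
    return nt.LSTMLayerParams(
        W_xi=z(hidden, inp), W_hi=z(hidden, hidden),
        W_xf=z(hidden, inp), W_hf=z(hidden, hidden),
        W_xo=z(hidden, inp), W_ho=z(hidden, hidden),
        W_xc=z(hidden, inp), W_hc=z(hidden, hidden),
        b_i=z(hidden), b_f=z(hidden), b_o=z(hidden), b_c=z(hidden),
    )


def _random_layer(rng, hidden, inp, scale=0.8):
    u = lambda *s: rng.uniform(-scale, scale, s)
    return nt.LSTMLayerParams(
        W_xi=u(hidden, inp), W_hi=u(hidden, hidden),
        W_xf=u(hidden, inp), W_hf=u(hidden, hidden),
        W_xo=u(hidden, inp), W_ho=u(hidden, hidden),
        W_xc=u(hidden, inp), W_hc=u(hidden, hidden),
        b_i=u(hidden), b_f=u(hidden), b_o=u(hidden), b_c=u(hidden),
    )


def _scalar_cell_oracle(x, h_prev, c_prev, p):
    """Pure-python elementwise evaluation of the gate equations."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    hd, xd = p.W_xi.shape
    h_out, c_out = [], []
    for k in range(hd):
        pre_i = sum(p.W_xi[k, j] * x[j] for j in range(xd)) \
            + sum(p.W_hi[k, j] * h_prev[j] for j in range(hd)) + p.b_i[k]
        pre_f = sum(p.W_xf[k, j] * x[j] for j in range(xd)) \
            + sum(p.W_hf[k, j] * h_prev[j] for j in range(hd)) + p.b_f[k]
        pre_o = sum(p.W_xo[k, j] * x[j] for j in range(xd)) \
            + sum(p.W_ho[k, j] * h_prev[j] for j in range(hd)) + p.b_o[k]
        pre_c = sum(p.W_xc[k, j] * x[j] for j in range(xd)) \
            + sum(p.W_hc[k, j] * h_prev[j] for j in range(hd)) + p.b_c[k]
        c_t = sig(pre_f) * c_prev[k] + sig(pre_i) * math.tanh(pre_c)
        c_out.append(c_t)
        h_out.append(sig(pre_o) * math.tanh(c_t))
    return h_out, c_out


class TestLstmCell:
    def test_zero_parameters_halve_memory(self):
        # all gates sit at sigmoid(0) = 1/2, so c_t = c_prev / 2
        p = _zero_layer()
        h, c = nt.lstm_cell_step(np.zeros(1), np.zeros(2), np.array([1.0, -2.0]), p)
        assert np.allclose(c, [0.5, -1.0])
        assert np.allclose(h, 0.5 * np.tanh(c))
        h0, c0 = nt.lstm_cell_step(np.zeros(1), np.zeros(2), np.zeros(2), p)
        assert np.allclose(h0, 0.0) and np.allclose(c0, 0.0)

    def test_saturated_forget_gate_carries_memory(self):
        p = _zero_layer()
        p.b_f[:] = 30.0  # forget gate pinned at ~1
        c_prev = np.array([0.7, -0.4])
        _, c = nt.lstm_cell_step(np.zeros(1), np.zeros(2), c_prev, p)
        assert np.allclose(c, c_prev, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hd = int(rng.integers(1, 4))
        p = _random_layer(rng, hd, 1)
        x = rng.uniform(-1, 1, 1)
        h_prev, c_prev = rng.uniform(-1, 1, hd), rng.uniform(-1, 1, hd)
        h, c = nt.lstm_cell_step(x, h_prev, c_prev, p)
        ho, co = _scalar_cell_oracle(x, h_prev, c_prev, p)
        assert np.allclose(h, ho, atol=1e-10) and np.allclose(c, co, atol=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            nt.lstm_cell_step(np.zeros(3), np.zeros(2), np.zeros(2), _zero_layer())


class TestLstmForward:
    def test_zero_parameters_give_zero_features(self):
        stack = [_zero_layer(2, 1), _zero_layer(2, 2)]
        assert np.allclose(nt.lstm_forward(np.ones(6), stack), 0.0)

    def test_depth_one_equals_chained_cell_steps(self, rng):
        p = _random_layer(rng, 2, 1)
        series = rng.uniform(-1, 1, 6)
        h, c = np.zeros(2), np.zeros(2)
        for t in range(6):
            h, c = nt.lstm_cell_step(series[t:t + 1], h, c, p)
        assert np.allclose(nt.lstm_forward(series, [p]), h, atol=1e-12)

    def test_last_two_steps_mode_returns_top_h5_h6(self, rng):
        p = _random_layer(rng, 1, 1)
        series = rng.uniform(-1, 1, 6)
        h, c = np.zeros(1), np.zeros(1)
        hs = []
        for t in range(6):
            h, c = nt.lstm_cell_step(series[t:t + 1], h, c, p)
            hs.append(h[0])
        feats = nt.lstm_forward(series, [p], mode="last_two_steps")
        assert np.allclose(feats, [hs[4], hs[5]], atol=1e-12)

    def test_default_depth10_is_finite_and_deterministic(self):
        cfg = nt.TrainConfig(lstm_depth=10, lstm_hidden=2)
        params = nt.init_params(cfg, np.random.default_rng(0))
        series = np.full(6, 0.3)
        a = nt.lstm_forward(series, params.lstm_stack)
        b = nt.lstm_forward(series, params.lstm_stack)
        assert np.array_equal(a, b) and np.all(np.isfinite(a))

    def test_wrong_sequence_length_raises(self):
        with pytest.raises(ValueError):
            nt.lstm_forward(np.zeros(5), [_zero_layer()])


class TestHybridForward:
    def _params(self, rng, depth=1, fc=(4, 3)):
        cfg = nt.TrainConfig(lstm_depth=depth, lstm_hidden=2, fc_hidden=fc)
        p = nt.init_params(cfg, rng)
        return p

    def test_all_zero_network_outputs_final_bias(self, rng):
        p = self._params(rng)
        for a in p.arrays():
            a[...] = 0.0
        p.fc_layers[-1].b[:] = 0.25
        out = nt.hybrid_forward(rng.uniform(-1, 1, 16), p)
        assert out == pytest.approx(0.25, abs=1e-12)

    def test_constructed_identity_path(self):
        # one unit chain with weight 1 passes a positive static input through
        cfg = nt.TrainConfig(lstm_depth=1, lstm_hidden=2, fc_hidden=(4, 3))
        p = nt.init_params(cfg, np.random.default_rng(0))
        for a in p.arrays():
            a[...] = 0.0
        # static feature 0 sits at x_init index 2 (after the 2 recurrent feats)
        p.fc_layers[0].W[0, 2] = 1.0
        p.fc_layers[1].W[0, 0] = 1.0
        p.fc_layers[2].W[0, 0] = 1.0
        x = np.zeros(16)
        x[0] = 0.6
        assert nt.hybrid_forward(x, p) == pytest.approx(0.6, abs=1e-12)

    def test_inference_is_deterministic(self, rng):
        p = self._params(rng)
        x = rng.uniform(-1, 1, (5, 16))
        assert np.array_equal(nt.hybrid_forward(x, p), nt.hybrid_forward(x, p))

    def test_unnormalized_input_warns(self, rng):
        p = self._params(rng)
        with pytest.warns(UserWarning, match="unnormalized"):
            nt.hybrid_forward(np.full(16, 3.0), p)

    def test_serialization_round_trip(self, rng, tmp_path):
        p = self._params(rng, depth=2)
        p.to_json(tmp_path / "m.json")
        q = nt.HybridNetParams.from_json(tmp_path / "m.json")
        x = rng.uniform(-1, 1, (4, 16))
        assert np.array_equal(nt.hybrid_forward(x, p), nt.hybrid_forward(x, q))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        cfg = nt.TrainConfig(lstm_depth=1, lstm_hidden=2, fc_hidden=(4, 3),
                             dropout_rate=0.0)
        p = nt.init_params(cfg, rng)
        for a in p.arrays():  # keep pre-activations off the ReLU kinks
            a += rng.uniform(-0.3, 0.3, a.shape)
        X = rng.uniform(-1, 1, (7, 16))
        y = rng.uniform(-1, 1, 7)
        _, grads = nt._loss_and_grads(p, X, y, training=False, rng=None)
        eps = 1e-6
        for ai, a in enumerate(p.arrays()):
            it = np.nditer(a, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = a[idx]
                a[idx] = orig + eps
                lp, _ = nt._loss_and_grads(p, X, y, training=False, rng=None)
                a[idx] = orig - eps
                lm, _ = nt._loss_and_grads(p, X, y, training=False, rng=None)
                a[idx] = orig
                num = (lp - lm) / (2 * eps)
                rel = abs(num - grads[ai][idx]) / max(1e-8, abs(num) + abs(grads[ai][idx]))
                assert rel < 1e-4


def _toy_problem(n=260, seed=3):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, (n, 16))
    y = 0.6 * X[:, 3] + 0.4 * X[:, 15] + rng.normal(0, 0.05, n)
    return X, np.clip(y, -1, 1)


class TestTraining:
    def test_infinite_min_error_stops_after_patience_epochs(self):
        X, y = _toy_problem()
        cfg = nt.TrainConfig(max_epochs=50, min_error=math.inf, lstm_depth=1,
                             patience_cycles=10, seed=0)
        _, log = nt.train(X, y, cfg)
        assert log["stop_reason"] == "patience"
        assert len(log["history"]) == 10

    def test_zero_min_error_runs_to_max_epochs(self):
        X, y = _toy_problem()
        cfg = nt.TrainConfig(max_epochs=5, min_error=0.0, lstm_depth=1, seed=0)
        _, log = nt.train(X, y, cfg)
        assert log["stop_reason"] == "max_epochs"
        assert len(log["history"]) == 5

    def test_fixed_seed_reproduces_training_trajectory(self):
        X, y = _toy_problem()
        cfg = nt.TrainConfig(max_epochs=3, lstm_depth=1, seed=11)
        p1, log1 = nt.train(X, y, cfg)
        p2, log2 = nt.train(X, y, cfg)
        assert log1["history"] == log2["history"]
        assert all(np.array_equal(a, b) for a, b in zip(p1.arrays(), p2.arrays()))

    def test_training_beats_constant_predictor(self):
        X, y = _toy_problem(n=400, seed=8)
        cfg = nt.TrainConfig(max_epochs=60, lstm_depth=1, seed=1)
        _, log = nt.train(X, y, cfg)
        assert log["best_val_mse"] < np.var(y)

    def test_divergent_labels_raise_with_epoch(self):
        X, y = _toy_problem(n=100)
        cfg = nt.TrainConfig(max_epochs=3, lstm_depth=1, seed=0)
        with pytest.raises(nt.TrainingDivergedError) as exc, \
                np.errstate(over="ignore"):
            nt.train(X, y * 1e200, cfg)
        assert exc.value.epoch >= 1

    def test_unlabelled_input_rejected(self):
        X, y = _toy_problem(n=100)
        with pytest.raises(ValueError):
            nt.train(X, np.full_like(y, np.nan), nt.TrainConfig(lstm_depth=1))


class TestWidthSelection:
    def test_single_width_gives_one_row(self):
        X, y = _toy_problem(n=120)
        cfg = nt.TrainConfig(max_epochs=2, lstm_depth=1, seed=0)
        table = nt.width_selection_experiment(X, y, [20], cfg)
        assert len(table) == 1 and table[0]["width"] == 20

    def test_identical_inputs_reproduce_table(self):
        X, y = _toy_problem(n=150)
        cfg = nt.TrainConfig(max_epochs=2, lstm_depth=1, seed=4)
        t1 = nt.width_selection_experiment(X, y, [12, 20], cfg)
        t2 = nt.width_selection_experiment(X, y, [12, 20], cfg)
        assert t1 == t2
        assert all(np.isfinite(r["val_mse"]) and r["val_mse"] > 0 for r in t1)
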