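"""Hybrid recurrent + fully-connected birthweight predictor.

The temporal branch is a stack of LSTM layers over the 6-step normalized
weight-change series.  Each cell follows the standard gate equations

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

with zero initial states.  The default stack is 10 layers of hidden width 2
with a scalar input per step; the two components of the top layer's final
hidden state are the recurrent features (x_h5, x_h6).  An alternate
extraction mode ("last_two_steps", hidden width 1) instead takes the top
layer's output at the last two time steps.

The static branch concatenates ReLU(x_h5, x_h6) with the 10 normalized
static predictors into a 12-vector feeding dense layers 12 -> 20 -> 12 -> 1
(ReLU between hidden layers, linear output, dropout 0.2 between hidden
dense layers during training only).

Training minimises mean squared error on the normalized label scale with
mini-batch Adam (batch size 50).  Gradients are hand-derived (standard
backpropagation-through-time); see tests for the finite-difference check.
Two stop conditions: reaching max_epochs, or validation error below the
predetermined minimum for 10 consecutive epochs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMLayerParams",
    "DenseLayerParams",
    "HybridNetParams",
    "TrainConfig",
    "TrainingDivergedError",
    "lstm_cell_step",
    "lstm_forward",
    "hybrid_forward",
    "init_params",
    "train",
    "predict_normalized",
    "predict",
    "width_selection_experiment",
]

N_SERIES = 6
N_STATIC = 10


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class LSTMLayerParams:
    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def input_dim(self) -> int:
        return self.W_xi.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W_xi.shape[0]

    def check_shapes(self) -> None:
        hd, xd = self.W_xi.shape
        for name in ("W_xi", "W_xf", "W_xo", "W_xc"):
            if getattr(self, name).shape != (hd, xd):
                raise ValueError(f"{name} shape mismatch")
        for name in ("W_hi", "W_hf", "W_ho", "W_hc"):
            if getattr(self, name).shape != (hd, hd):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (hd,):
                raise ValueError(f"{name} shape mismatch")

    def arrays(self):
        return [self.W_xi, self.W_hi, self.W_xf, self.W_hf, self.W_xo,
                self.W_ho, self.W_xc, self.W_hc,
                self.b_i, self.b_f, self.b_o, self.b_c]


@dataclass
class DenseLayerParams:
    W: np.ndarray  # (out, in)
    b: np.ndarray  # (out,)

    def arrays(self):
        return [self.W, self.b]


@dataclass
class HybridNetParams:
    lstm_stack: list
    fc_layers: list
    dropout_rate: float = 0.2
    mode: str = "final_state"  # or "last_two_steps"

    def arrays(self):
        out = []
        for layer in self.lstm_stack:
            out += layer.arrays()
        for layer in self.fc_layers:
            out += layer.arrays()
        return out

    @property
    def feature_dim(self) -> int:
        if self.mode == "final_state":
            return self.lstm_stack[-1].hidden_dim
        return 2

    def validate(self) -> None:
        for layer in self.lstm_stack:
            layer.check_shapes()
        expect = self.feature_dim + N_STATIC
        if self.fc_layers[0].W.shape[1] != expect:
            raise ValueError(
                f"first dense layer expects input dim {expect}, "
                f"got {self.fc_layers[0].W.shape[1]}"
            )
        if self.fc_layers[-1].W.shape[0] != 1:
            raise ValueError("final dense layer must have 1 output")

    def to_json(self, path) -> None:
        def pack(a):
            return {"shape": list(a.shape), "data": [float(v) for v in a.ravel()]}

        payload = {
            "mode": self.mode,
            "dropout_rate": self.dropout_rate,
            "lstm_stack": [
                {k: pack(getattr(layer, k)) for k in
                 ("W_xi", "W_hi", "W_xf", "W_hf", "W_xo", "W_ho", "W_xc", "W_hc",
                  "b_i", "b_f", "b_o", "b_c")}
                for layer in self.lstm_stack
            ],
            "fc_layers": [{"W": pack(l.W), "b": pack(l.b)} for l in self.fc_layers],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "HybridNetParams":
        def unpack(d):
            return np.asarray(d["data"], dtype=float).reshape(d["shape"])

        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        stack = [LSTMLayerParams(**{k: unpack(v) for k, v in layer.items()})
                 for layer in payload["lstm_stack"]]
        fc = [DenseLayerParams(W=unpack(l["W"]), b=unpack(l["b"]))
              for l in payload["fc_layers"]]
        return cls(lstm_stack=stack, fc_layers=fc,
                   dropout_rate=payload["dropout_rate"], mode=payload["mode"])


@dataclass
class TrainConfig:
    max_epochs: int = 200
    min_error: float = 1e-4
    patience_cycles: int = 10
    batch_size: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    validation_fraction: float = 0.2
    early_stop_mode: str = "threshold"  # or "plateau"
    restore_best: bool = True  # roll back to the best-validation epoch
    lstm_depth: int = 10
    lstm_hidden: int = 2
    fc_hidden: tuple = (20, 12)
    dropout_rate: float = 0.2
    mode: str = "final_state"

    def validate(self) -> None:
        if min(self.max_epochs, self.patience_cycles, self.batch_size) < 1:
            raise ValueError("max_epochs, patience_cycles, batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


def init_params(cfg: TrainConfig, rng: np.random.Generator) -> HybridNetParams:
    """Uniform fan-in initialization; forget-gate biases start at 1."""
    def uni(rows, cols):
        bound = 1.0 / math.sqrt(max(cols, 1))
        return rng.uniform(-bound, bound, size=(rows, cols))

    hidden = 1 if cfg.mode == "last_two_steps" else cfg.lstm_hidden
    stack = []
    in_dim = 1
    for _ in range(cfg.lstm_depth):
        stack.append(LSTMLayerParams(
            W_xi=uni(hidden, in_dim), W_hi=uni(hidden, hidden),
            W_xf=uni(hidden, in_dim), W_hf=uni(hidden, hidden),
            W_xo=uni(hidden, in_dim), W_ho=uni(hidden, hidden),
            W_xc=uni(hidden, in_dim), W_hc=uni(hidden, hidden),
            b_i=np.zeros(hidden), b_f=np.ones(hidden),
            b_o=np.zeros(hidden), b_c=np.zeros(hidden),
        ))
        in_dim = hidden
    feature_dim = hidden if cfg.mode == "final_state" else 2
    dims = (feature_dim + N_STATIC,) + tuple(cfg.fc_hidden) + (1,)
    fc = [DenseLayerParams(W=uni(dims[i + 1], dims[i]), b=np.zeros(dims[i + 1]))
          for i in range(len(dims) - 1)]
    params = HybridNetParams(lstm_stack=stack, fc_layers=fc,
                             dropout_rate=cfg.dropout_rate, mode=cfg.mode)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# forward passes

def lstm_cell_step(x_t, h_prev, c_prev, params: LSTMLayerParams):
    """One gate update; accepts a single vector or a (batch, dim) array."""
    single = np.asarray(x_t).ndim == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    if x_t.shape[1] != params.input_dim or h_prev.shape[1] != params.hidden_dim:
        raise ValueError("input/state dimension mismatch with layer parameters")
    i = _sigmoid(x_t @ params.W_xi.T + h_prev @ params.W_hi.T + params.b_i)
    f = _sigmoid(x_t @ params.W_xf.T + h_prev @ params.W_hf.T + params.b_f)
    o = _sigmoid(x_t @ params.W_xo.T + h_prev @ params.W_ho.T + params.b_o)
    g = np.tanh(x_t @ params.W_xc.T + h_prev @ params.W_hc.T + params.b_c)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return (h[0], c[0]) if single else (h, c)


def _stack_forward(series, stack, cache=None):
    """Run a (B, T) scalar series through the stacked layers.

    Returns the per-layer h sequences; optionally fills ``cache`` with every
    intermediate needed for backpropagation.
    """
    B, T = series.shape
    X = series[:, :, None]  # layer-0 input, feature dim 1
    h_seqs = []
    for li, p in enumerate(stack):
        hd = p.hidden_dim
        h = np.zeros((B, hd))
        c = np.zeros((B, hd))
        hs = np.empty((B, T, hd))
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            i = _sigmoid(x_t @ p.W_xi.T + h @ p.W_hi.T + p.b_i)
            f = _sigmoid(x_t @ p.W_xf.T + h @ p.W_hf.T + p.b_f)
            o = _sigmoid(x_t @ p.W_xo.T + h @ p.W_ho.T + p.b_o)
            g = np.tanh(x_t @ p.W_xc.T + h @ p.W_hc.T + p.b_c)
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if cache is not None:
                steps.append((x_t, h, c, i, f, o, g, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        if cache is not None:
            cache.append({"steps": steps, "input": X, "h_seq": hs})
        h_seqs.append(hs)
        X = hs
    return h_seqs


def _extract_features(h_seqs, mode):
    top = h_seqs[-1]
    if mode == "final_state":
        return top[:, -1, :]
    if mode == "last_two_steps":
        if top.shape[2] != 1:
            raise ValueError("last_two_steps mode requires hidden width 1")
        return np.concatenate([top[:, -2, :], top[:, -1, :]], axis=1)
    raise ValueError(f"unknown feature extraction mode {mode!r}")


def lstm_forward(series, stack, mode: str = "final_state"):
    """Recurrent features (x_h5, x_h6) for a (B, 6) or (6,) series."""
    series = np.asarray(series, dtype=float)
    single = series.ndim == 1
    series = np.atleast_2d(series)
    if series.shape[1] != N_SERIES:
        raise ValueError(f"expected sequence length {N_SERIES}, got {series.shape[1]}")
    feats = _extract_features(_stack_forward(series, stack), mode)
    return feats[0] if single else feats


def _dense_forward(x, params: HybridNetParams, training, rng, cache=None):
    n_layers = len(params.fc_layers)
    for li, layer in enumerate(params.fc_layers):
        s = x @ layer.W.T + layer.b
        last = li == n_layers - 1
        a = s if last else np.maximum(s, 0.0)
        mask = None
        if training and not last and params.dropout_rate > 0.0:
            keep = 1.0 - params.dropout_rate
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
        if cache is not None:
            cache.append((x, s, mask))
        x = a
    return x[:, 0]


def hybrid_forward(X, params: HybridNetParams, training: bool = False,
                   rng: np.random.Generator | None = None):
    """Predict on the normalized scale from (B, 16) normalized features.

    Columns 0..9 are the static predictors, 10..15 the weight-change series.
    Inference (training=False) is deterministic; dropout only acts in
    training mode between the hidden dense layers.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != N_STATIC + N_SERIES:
        raise ValueError(f"expected {N_STATIC + N_SERIES} features, got {X.shape[1]}")
    if np.any(np.abs(X) > 1.0 + 1e-6):
        import warnings

        warnings.warn("feature values outside [-1, 1]; inputs may be unnormalized")
    if training and rng is None:
        rng = np.random.default_rng(0)
    static, series = X[:, :N_STATIC], X[:, N_STATIC:]
    feats = _extract_features(_stack_forward(series, params.lstm_stack), params.mode)
    x_init = np.concatenate([np.maximum(feats, 0.0), static], axis=1)
    out = _dense_forward(x_init, params, training, rng)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# backward pass

def _zeros_like_params(params: HybridNetParams):
    return [np.zeros_like(a) for a in params.arrays()]


def _loss_and_grads(params: HybridNetParams, X, y, training, rng):
    """MSE loss and gradients for one mini-batch (hand-derived backprop)."""
    B = X.shape[0]
    static, series = X[:, :N_STATIC], X[:, N_STATIC:]
    cache: list = []
    h_seqs = _stack_forward(series, params.lstm_stack, cache=cache)
    feats = _extract_features(h_seqs, params.mode)
    relu_feats = np.maximum(feats, 0.0)
    x_init = np.concatenate([relu_feats, static], axis=1)

    dense_cache: list = []
    out = _dense_forward(x_init, params, training, rng, cache=dense_cache)
    resid = out - y
    loss = float(np.mean(resid ** 2))

    grads_fc = []
    d_out = (2.0 / B) * resid
    d_a = d_out[:, None]
    n_layers = len(params.fc_layers)
    for li in range(n_layers - 1, -1, -1):
        x_in, s, mask = dense_cache[li]
        last = li == n_layers - 1
        if last:
            d_s = d_a
        else:
            if mask is not None:
                d_a = d_a * mask
            d_s = d_a * (s > 0.0)
        layer = params.fc_layers[li]
        grads_fc.append([d_s.T @ x_in, d_s.sum(axis=0)])
        d_a = d_s @ layer.W
    grads_fc.reverse()

    d_x_init = d_a
    fd = params.feature_dim if params.mode == "final_state" else 2
    d_feats = d_x_init[:, :fd] * (feats > 0.0)

    T = series.shape[1]
    n_stack = len(params.lstm_stack)
    # per-step external gradient on the top layer's h outputs
    d_h_ext = [np.zeros_like(h_seqs[-1][:, 0, :]) for _ in range(T)]
    if params.mode == "final_state":
        d_h_ext[T - 1] = d_feats
    else:
        d_h_ext[T - 2] = d_feats[:, 0:1]
        d_h_ext[T - 1] = d_feats[:, 1:2]

    grads_lstm = [None] * n_stack
    for li in range(n_stack - 1, -1, -1):
        p = params.lstm_stack[li]
        steps = cache[li]["steps"]
        gW = {k: np.zeros_like(getattr(p, k)) for k in
              ("W_xi", "W_hi", "W_xf", "W_hf", "W_xo", "W_ho", "W_xc", "W_hc",
               "b_i", "b_f", "b_o", "b_c")}
        d_input = np.zeros_like(cache[li]["input"])
        dh_carry = np.zeros((B, p.hidden_dim))
        dc_carry = np.zeros((B, p.hidden_dim))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, o, g, tanh_c = steps[t]
            dh = dh_carry + d_h_ext[t]
            dc = dc_carry + dh * o * (1.0 - tanh_c ** 2)
            d_o = dh * tanh_c
            d_i = dc * g
            d_f = dc * c_prev
            d_g = dc * i
            dc_carry = dc * f
            da_i = d_i * i * (1.0 - i)
            da_f = d_f * f * (1.0 - f)
            da_o = d_o * o * (1.0 - o)
            da_g = d_g * (1.0 - g ** 2)
            gW["W_xi"] += da_i.T @ x_t
            gW["W_hi"] += da_i.T @ h_prev
            gW["b_i"] += da_i.sum(axis=0)
            gW["W_xf"] += da_f.T @ x_t
            gW["W_hf"] += da_f.T @ h_prev
            gW["b_f"] += da_f.sum(axis=0)
            gW["W_xo"] += da_o.T @ x_t
            gW["W_ho"] += da_o.T @ h_prev
            gW["b_o"] += da_o.sum(axis=0)
            gW["W_xc"] += da_g.T @ x_t
            gW["W_hc"] += da_g.T @ h_prev
            gW["b_c"] += da_g.sum(axis=0)
            d_input[:, t, :] = (da_i @ p.W_xi + da_f @ p.W_xf
                                + da_o @ p.W_xo + da_g @ p.W_xc)
            dh_carry = (da_i @ p.W_hi + da_f @ p.W_hf
                        + da_o @ p.W_ho + da_g @ p.W_hc)
        grads_lstm[li] = [gW[k] for k in
                          ("W_xi", "W_hi", "W_xf", "W_hf", "W_xo", "W_ho",
                           "W_xc", "W_hc", "b_i", "b_f", "b_o", "b_c")]
        if li > 0:
            d_h_ext = [d_input[:, t, :] for t in range(T)]

    flat = []
    for g in grads_lstm:
        flat += g
    for g in grads_fc:
        flat += g
    return loss, flat


class _Adam:
    def __init__(self, arrays, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _SGD:
    def __init__(self, arrays, lr):
        self.lr = lr

    def step(self, arrays, grads):
        for a, g in zip(arrays, grads):
            a -= self.lr * g


def train(X, y, cfg: TrainConfig, params: HybridNetParams | None = None):
    """Fit the hybrid network on normalized features/labels.

    Returns (params, log) where log is a dict with per-epoch ``history``
    rows (epoch, train_mse, val_mse) and the ``stop_reason``
    ("max_epochs" or "patience").
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < cfg.batch_size:
        raise ValueError("need at least batch_size labelled examples")
    if np.any(~np.isfinite(y)):
        raise ValueError("labels must be finite (normalized birthweights)")

    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_params(cfg, rng)
    arrays = params.arrays()

    n = len(X)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    opt_cls = {"adam": _Adam, "sgd": _SGD}.get(cfg.optimizer.lower())
    if opt_cls is None:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    opt = opt_cls(arrays, cfg.learning_rate)

    history = []
    stop_reason = "max_epochs"
    streak = 0
    best_val = math.inf
    best_snapshot = None
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(X_tr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(X_tr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = _loss_and_grads(params, X_tr[idx], y_tr[idx],
                                          training=True, rng=rng)
            if not math.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.step(arrays, grads)
            epoch_loss += loss
            n_batches += 1
        val_pred = hybrid_forward(X_val, params, training=False)
        val_mse = float(np.mean((val_pred - y_val) ** 2))
        if not math.isfinite(val_mse):
            raise TrainingDivergedError(epoch)
        history.append({"epoch": epoch,
                        "train_mse": epoch_loss / max(n_batches, 1),
                        "val_mse": val_mse})
        improved = val_mse < best_val - 1e-12
        if improved:
            best_val = val_mse
            if cfg.restore_best:
                best_snapshot = [a.copy() for a in arrays]
        if cfg.early_stop_mode == "threshold":
            streak = streak + 1 if val_mse < cfg.min_error else 0
        else:  # plateau: epochs without improvement
            streak = 0 if improved else streak + 1
        if streak >= cfg.patience_cycles:
            stop_reason = "patience"
            break
    if cfg.restore_best and best_snapshot is not None:
        for a, snap in zip(arrays, best_snapshot):
            a[...] = snap
    return params, {"history": history, "stop_reason": stop_reason,
                    "best_val_mse": best_val,
                    "n_train": len(X_tr), "n_val": n_val}


def predict_normalized(X, params: HybridNetParams):
    return hybrid_forward(X, params, training=False)


def predict(X, params: HybridNetParams, label_entry: tuple[float, float]):
    """Predictions in grams: forward pass then inverse min-max transform."""
    from .preprocess import denormalize_scalar

    out = np.atleast_1d(hybrid_forward(X, params, training=False))
    return np.array([denormalize_scalar(v, label_entry) for v in out])


def width_selection_experiment(X, y, widths, cfg: TrainConfig):
    """Validation MSE of the trained net per second-dense-layer width.

    All runs share the data, seed and epoch budget; returns a list of
    {"width": w, "val_mse": m} rows (the published analogue selects the
    width with the minimum MSE, 20 in the reference experiment).
    """
    if not widths:
        raise ValueError("widths must be non-empty")
    rows = []
    for w in widths:
        run_cfg = TrainConfig(**{**cfg.__dict__, "fc_hidden": (int(w),) + tuple(cfg.fc_hidden[1:])})
        _, log = train(X, y, run_cfg)
        best = min(h["val_mse"] for h in log["history"])
        rows.append({"width": int(w), "val_mse": best})
    return rows
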