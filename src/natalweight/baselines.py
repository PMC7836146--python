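"""Reference birthweight predictors.

* Zhuo's empirical formula: G = uh * 100 grams, with uh the uterine (fundal)
  height in cm — the clinical single-measurement baseline.
* Ordinary least squares linear regression on the 16 normalized features.
* Configured machine-learning families (SVR, random forest, back-propagation
  neural network, 1-D CNN), each with the reference hyperparameter set; the
  SVR/RF internals delegate to scikit-learn, while BPNN/CNN run on this
  package's own network engine.

All baselines emit predictions in grams over the same feature rows, so they
are directly comparable with the hybrid model in one report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaselineConfig",
    "zhuo_predict",
    "linear_fit",
    "linear_predict",
    "fit_reference_model",
    "BASELINE_KINDS",
    "TABLE_DEFAULTS",
]

BASELINE_KINDS = ("zhuo", "linear", "svr", "rf", "bpnn", "cnn")

#: Reference hyperparameter sets per model family.
TABLE_DEFAULTS: dict[str, dict] = {
    "zhuo": {},
    "linear": {"fit_intercept": True},
    "svr": {"kernel": "linear", "C": 1.0, "cache_size": 200, "tol": 0.001,
            "gamma": "scale"},
    "rf": {"n_estimators": 200, "min_samples_leaf": 1, "min_samples_split": 2,
           "max_depth": None, "max_features": 7},
    "bpnn": {"kernel_initializer": "uniform", "activation1": "relu",
             "activation2": "sigmoid", "optimizer": "adam", "epochs": 200,
             "batch_size": 128, "hidden_units": 16, "learning_rate": 1e-3},
    "cnn": {"lr": 0.01, "epochs": 100, "optimizer": "adam",
            "conv1_in_channels": 1, "conv1_out_channels": 10,
            "conv1_kernel_size": 1, "conv1_stride": 2,
            "conv2_in_channels": 10, "conv2_out_channels": 20,
            "conv2_kernel_size": 1, "conv2_stride": 2,
            "batch_size": 50},
}


@dataclass
class BaselineConfig:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def resolved(self) -> dict:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        return {**TABLE_DEFAULTS[self.kind], **self.hyperparameters}


def zhuo_predict(uh):
    """Empirical fundal-height formula: predicted grams = uh [cm] * 100."""
    uh = np.asarray(uh, dtype=float)
    if np.any(uh <= 0):
        raise ValueError("uterine height must be positive")
    out = uh * 100.0
    return float(out) if out.ndim == 0 else out


def linear_fit(X, y):
    """OLS with intercept; returns (intercept, coefficient vector).

    Rank-deficient designs fall back to the minimum-norm solution (what
    scikit-learn's lstsq-based solver produces) with a logged warning.
    """
    from sklearn.linear_model import LinearRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        import logging

        logging.getLogger(__name__).warning(
            "rank-deficient design: using minimum-norm least-squares solution")
    model = LinearRegression(fit_intercept=True).fit(X, y)
    return float(model.intercept_), model.coef_.copy()


def linear_predict(X, intercept: float, coefs: np.ndarray):
    return np.asarray(X, dtype=float) @ np.asarray(coefs, dtype=float) + intercept


# ---------------------------------------------------------------------------
# small feed-forward trainers for the BPNN and CNN families

def _uniform(rng, rows, cols):
    bound = 1.0 / math.sqrt(max(cols, 1))
    return rng.uniform(-bound, bound, size=(rows, cols))


class _BPNN:
    """Standard 3-layer network: relu hidden layer, sigmoid output unit.

    Labels are min-max scaled to (0, 1) internally to match the sigmoid
    output; trained with mini-batch Adam on MSE.
    """

    def __init__(self, hp: dict, seed: int):
        self.hp = hp
        self.seed = seed

    def fit(self, X, y):
        from .network import _Adam

        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self._ylo, self._yhi = float(y.min()), float(y.max())
        span = max(self._yhi - self._ylo, 1e-9)
        yt = 0.05 + 0.9 * (y - self._ylo) / span  # keep off the sigmoid tails
        rng = np.random.default_rng(self.seed)
        h = int(self.hp["hidden_units"])
        self.W1 = _uniform(rng, h, X.shape[1]); self.b1 = np.zeros(h)
        self.W2 = _uniform(rng, 1, h); self.b2 = np.zeros(1)
        arrays = [self.W1, self.b1, self.W2, self.b2]
        opt = _Adam(arrays, self.hp["learning_rate"])
        bs = int(self.hp["batch_size"])
        for _ in range(int(self.hp["epochs"])):
            order = rng.permutation(len(X))
            for s in range(0, len(X), bs):
                idx = order[s:s + bs]
                xb, yb = X[idx], yt[idx]
                a1 = np.maximum(xb @ self.W1.T + self.b1, 0.0)
                z2 = a1 @ self.W2.T + self.b2
                p = 1.0 / (1.0 + np.exp(-z2))
                resid = p[:, 0] - yb
                d_z2 = (2.0 / len(xb)) * resid[:, None] * p * (1.0 - p)
                gW2 = d_z2.T @ a1; gb2 = d_z2.sum(axis=0)
                d_a1 = d_z2 @ self.W2
                d_s1 = d_a1 * (a1 > 0.0)
                gW1 = d_s1.T @ xb; gb1 = d_s1.sum(axis=0)
                opt.step(arrays, [gW1, gb1, gW2, gb2])
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        a1 = np.maximum(X @ self.W1.T + self.b1, 0.0)
        p = 1.0 / (1.0 + np.exp(-(a1 @ self.W2.T + self.b2)))[:, 0]
        span = max(self._yhi - self._ylo, 1e-9)
        return (p - 0.05) / 0.9 * span + self._ylo


class _CNN1D:
    """Two kernel-size-1, stride-2 conv blocks over the 16-feature signal.

    A kernel-1 convolution is a per-position channel mix, so each block is a
    strided pointwise linear map followed by ReLU; a linear readout maps the
    flattened channels to the prediction.
    """

    def __init__(self, hp: dict, seed: int):
        self.hp = hp
        self.seed = seed

    @staticmethod
    def _conv(x, W, b, stride):
        # x: (B, C_in, L) -> (B, C_out, ceil(L/stride)) with kernel size 1
        xs = x[:, :, ::stride]
        return np.einsum("oc,bcl->bol", W, xs) + b[None, :, None], xs

    def fit(self, X, y):
        from .network import _Adam

        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self._ymu, self._ysd = float(y.mean()), float(max(y.std(), 1e-9))
        yt = (y - self._ymu) / self._ysd
        rng = np.random.default_rng(self.seed)
        hp = self.hp
        c1o, c2o = int(hp["conv1_out_channels"]), int(hp["conv2_out_channels"])
        L = X.shape[1]
        l1 = -(-L // int(hp["conv1_stride"]))
        l2 = -(-l1 // int(hp["conv2_stride"]))
        self.W1 = _uniform(rng, c1o, int(hp["conv1_in_channels"])); self.b1 = np.zeros(c1o)
        self.W2 = _uniform(rng, c2o, c1o); self.b2 = np.zeros(c2o)
        self.W3 = _uniform(rng, 1, c2o * l2); self.b3 = np.zeros(1)
        arrays = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]
        opt = _Adam(arrays, hp["lr"])
        bs = int(hp["batch_size"])
        s1, s2 = int(hp["conv1_stride"]), int(hp["conv2_stride"])
        for _ in range(int(hp["epochs"])):
            order = rng.permutation(len(X))
            for s in range(0, len(X), bs):
                idx = order[s:s + bs]
                xb = X[idx][:, None, :]  # (B, 1, L)
                yb = yt[idx]
                z1, x1s = self._conv(xb, self.W1, self.b1, s1)
                a1 = np.maximum(z1, 0.0)
                z2, x2s = self._conv(a1, self.W2, self.b2, s2)
                a2 = np.maximum(z2, 0.0)
                flat = a2.reshape(len(xb), -1)
                out = flat @ self.W3.T + self.b3
                resid = out[:, 0] - yb
                d_out = (2.0 / len(xb)) * resid[:, None]
                gW3 = d_out.T @ flat; gb3 = d_out.sum(axis=0)
                d_a2 = (d_out @ self.W3).reshape(a2.shape) * (z2 > 0.0)
                gW2 = np.einsum("bol,bcl->oc", d_a2, x2s); gb2 = d_a2.sum(axis=(0, 2))
                d_x2s = np.einsum("oc,bol->bcl", self.W2, d_a2)
                d_a1 = np.zeros_like(a1); d_a1[:, :, ::s2] = d_x2s
                d_z1 = d_a1 * (z1 > 0.0)
                gW1 = np.einsum("bol,bcl->oc", d_z1, x1s); gb1 = d_z1.sum(axis=(0, 2))
                opt.step(arrays, [gW1, gb1, gW2, gb2, gW3, gb3])
        return self

    def predict(self, X):
        X = np.asarray(X, float)[:, None, :]
        s1, s2 = int(self.hp["conv1_stride"]), int(self.hp["conv2_stride"])
        a1 = np.maximum(self._conv(X, self.W1, self.b1, s1)[0], 0.0)
        a2 = np.maximum(self._conv(a1, self.W2, self.b2, s2)[0], 0.0)
        out = a2.reshape(len(X), -1) @ self.W3.T + self.b3
        return out[:, 0] * self._ysd + self._ymu


class _ZhuoModel:
    """Training-free wrapper; expects the raw uterine height as input."""

    def fit(self, X, y):
        return self

    def predict(self, uh):
        return zhuo_predict(uh)


class _LinearModel:
    def fit(self, X, y):
        self.intercept_, self.coef_ = linear_fit(X, y)
        return self

    def predict(self, X):
        return linear_predict(X, self.intercept_, self.coef_)


def fit_reference_model(cfg: BaselineConfig, X, y):
    """Fit the named baseline family with its reference hyperparameters.

    Returns an object with a ``predict(X) -> grams`` method.  For "zhuo" the
    input is the raw uterine height; all other kinds take the feature matrix
    and labels in grams.
    """
    hp = cfg.resolved()
    if cfg.kind == "zhuo":
        return _ZhuoModel().fit(X, y)
    if cfg.kind == "linear":
        return _LinearModel().fit(X, y)
    if cfg.kind == "svr":
        from sklearn.svm import SVR

        return SVR(**hp).fit(X, y)
    if cfg.kind == "rf":
        from sklearn.ensemble import RandomForestRegressor

        hp = dict(hp)
        hp["max_features"] = min(int(hp["max_features"]), np.asarray(X).shape[1])
        return RandomForestRegressor(random_state=cfg.seed, **hp).fit(X, y)
    if cfg.kind == "bpnn":
        return _BPNN(hp, seed=cfg.seed).fit(X, y)
    if cfg.kind == "cnn":
        return _CNN1D(hp, seed=cfg.seed).fit(X, y)
    raise ValueError(f"unknown baseline kind {cfg.kind!r}")
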