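"""Seeded minibatch neural networks in NumPy.

Three small families cover the classifier comparison: a dense softmax network
(the wavelet-feature and raw-band-power classifiers), a 1-D convolutional
network, and an LSTM. All expose the same training knobs — ``batch_size``,
``epochs``, ``optimizer`` (adam / rmsprop), ``init_mode`` (uniform /
lecun_uniform / normal), ``activation`` (relu / tanh), ``neurons`` — and every
stochastic step (weight init, batch shuffling, dropout) is driven by one
``numpy`` Generator, so training is bit-reproducible under a seed on a single
thread.

Loss is categorical cross-entropy; prediction is the arg-max class, ties
resolved toward the lowest class index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, TrainingError


# ----------------------------------------------------------------- pieces
def _init(shape: tuple[int, ...], mode: str, rng: np.random.Generator) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    if mode == "uniform":
        return rng.uniform(-0.05, 0.05, size=shape)
    if mode == "lecun_uniform":
        limit = np.sqrt(3.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape)
    if mode == "normal":
        return rng.normal(0.0, 0.05, size=shape)
    raise ConfigurationError(f"unknown init_mode {mode!r}")


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "tanh":
        return np.tanh(x)
    raise ConfigurationError(f"unknown activation {kind!r}")


def _act_grad(out: np.ndarray, kind: str) -> np.ndarray:
    return (out > 0).astype(float) if kind == "relu" else 1.0 - out**2


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


class _Optimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.state: dict[str, dict[str, np.ndarray]] = {
            k: {s: np.zeros_like(v) for s in self.slots} for k, v in params.items()
        }
        self.t = 0

    slots: tuple[str, ...] = ()

    def step(self, grads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    slots = ("m", "v")

    def step(self, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-7
        for k, g in grads.items():
            st = self.state[k]
            st["m"] = b1 * st["m"] + (1 - b1) * g
            st["v"] = b2 * st["v"] + (1 - b2) * g**2
            mhat = st["m"] / (1 - b1**self.t)
            vhat = st["v"] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class RMSprop(_Optimizer):
    slots = ("v",)

    def step(self, grads):
        rho, eps = 0.9, 1e-7
        for k, g in grads.items():
            st = self.state[k]
            st["v"] = rho * st["v"] + (1 - rho) * g**2
            self.params[k] -= self.lr * g / (np.sqrt(st["v"]) + eps)


_OPTIMIZERS = {"adam": Adam, "rmsprop": RMSprop}


@dataclass
class TrainSettings:
    """The shared training knobs (the randomized-search grid's axes plus lr)."""

    batch_size: int = 20
    epochs: int = 20
    optimizer: str = "adam"
    init_mode: str = "lecun_uniform"
    activation: str = "relu"
    neurons: int = 64
    lr: float = 0.005

    def __post_init__(self):
        if self.optimizer not in _OPTIMIZERS:
            raise ConfigurationError(f"optimizer must be one of {list(_OPTIMIZERS)}")
        if self.batch_size < 1 or self.epochs < 1 or self.neurons < 2:
            raise ConfigurationError("batch_size/epochs/neurons out of range")


# ----------------------------------------------------------------- networks
class _BaseNet:
    """Shared minibatch training loop. Subclasses define build/forward/backward."""

    def __init__(self, n_classes: int, settings: TrainSettings, seed: int):
        self.n_classes = n_classes
        self.settings = settings
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self._rng = np.random.default_rng(seed)

    # subclass API -------------------------------------------------
    def _build(self, input_shape: tuple[int, ...]) -> None:
        raise NotImplementedError

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return X

    # training -----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseNet":
        X = self._prepare(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise TrainingError("X and y length mismatch")
        if not self.params:
            self._build(X.shape[1:])
        s = self.settings
        opt = _OPTIMIZERS[s.optimizer](self.params, s.lr)
        n = len(X)
        onehot = np.eye(self.n_classes)[y]
        for _ in range(s.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, s.batch_size):
                idx = order[start : start + s.batch_size]
                logits, cache = self._forward(X[idx], train=True)
                probs = _softmax(logits)
                dlogits = (probs - onehot[idx]) / len(idx)
                opt.step(self._backward(cache, dlogits))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(np.asarray(X, dtype=float))
        logits, _ = self._forward(X, train=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)  # first max -> lowest index

    # serialization ------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=float).copy() for k, v in weights.items()}


class DenseNet(_BaseNet):
    """input -> dense(neurons, act) -> dropout(0.2) -> dense(neurons//2, act) -> softmax."""

    dropout = 0.2

    def _build(self, input_shape):
        (d,) = input_shape
        s = self.settings
        h1, h2 = s.neurons, max(2, s.neurons // 2)
        self.params = {
            "W1": _init((d, h1), s.init_mode, self._rng),
            "b1": np.zeros(h1),
            "W2": _init((h1, h2), s.init_mode, self._rng),
            "b2": np.zeros(h2),
            "W3": _init((h2, self.n_classes), s.init_mode, self._rng),
            "b3": np.zeros(self.n_classes),
        }

    def _forward(self, X, train):
        act = self.settings.activation
        a1 = _act(X @ self.params["W1"] + self.params["b1"], act)
        if train and self.dropout > 0:
            mask = (self._rng.random(a1.shape) >= self.dropout) / (1 - self.dropout)
            a1d = a1 * mask
        else:
            mask = None
            a1d = a1
        a2 = _act(a1d @ self.params["W2"] + self.params["b2"], act)
        logits = a2 @ self.params["W3"] + self.params["b3"]
        return logits, {"X": X, "a1": a1, "mask": mask, "a1d": a1d, "a2": a2}

    def _backward(self, c, dlogits):
        act = self.settings.activation
        g = {}
        g["W3"] = c["a2"].T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        da2 = dlogits @ self.params["W3"].T * _act_grad(c["a2"], act)
        g["W2"] = c["a1d"].T @ da2
        g["b2"] = da2.sum(axis=0)
        da1 = da2 @ self.params["W2"].T
        if c["mask"] is not None:
            da1 = da1 * c["mask"]
        da1 = da1 * _act_grad(c["a1"], act)
        g["W1"] = c["X"].T @ da1
        g["b1"] = da1.sum(axis=0)
        return g


def reshape_to_sequence(X: np.ndarray, n_steps: int = 8) -> np.ndarray:
    """[n, p] -> [n, n_steps, ceil(p/n_steps)] with zero padding (flat inputs
    fed to sequence models)."""
    if X.ndim == 3:
        return X
    n, p = X.shape
    d = int(np.ceil(p / n_steps))
    pad = n_steps * d - p
    if pad:
        X = np.concatenate([X, np.zeros((n, pad))], axis=1)
    return X.reshape(n, n_steps, d)


class LSTMNet(_BaseNet):
    """LSTM(neurons) over the input sequence -> last hidden state -> softmax."""

    def _prepare(self, X):
        return reshape_to_sequence(X)

    def _build(self, input_shape):
        _, d = input_shape
        s = self.settings
        h = s.neurons
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.params = {
            "Wx": _init((d, 4 * h), s.init_mode, self._rng),
            "Wh": _init((h, 4 * h), s.init_mode, self._rng),
            "b": b,
            "Wo": _init((h, self.n_classes), s.init_mode, self._rng),
            "bo": np.zeros(self.n_classes),
        }

    def _forward(self, X, train):
        B, T, _ = X.shape
        h = self.params["Wh"].shape[0]
        hs = np.zeros((B, h))
        cs = np.zeros((B, h))
        steps = []
        for t in range(T):
            z = X[:, t] @ self.params["Wx"] + hs @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            o = _sigmoid(z[:, 2 * h : 3 * h])
            g = np.tanh(z[:, 3 * h :])
            c_new = f * cs + i * g
            h_new = o * np.tanh(c_new)
            steps.append({"x": X[:, t], "h_prev": hs, "c_prev": cs, "i": i, "f": f, "o": o, "g": g, "c": c_new})
            hs, cs = h_new, c_new
        logits = hs @ self.params["Wo"] + self.params["bo"]
        return logits, {"steps": steps, "h_last": hs}

    def _backward(self, cache, dlogits):
        p = self.params
        h = p["Wh"].shape[0]
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = cache["h_last"].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T
        dc = np.zeros_like(dh)
        for st in reversed(cache["steps"]):
            tanh_c = np.tanh(st["c"])
            do = dh * tanh_c
            dc = dc + dh * st["o"] * (1 - tanh_c**2)
            di = dc * st["g"]
            df = dc * st["c_prev"]
            dg = dc * st["i"]
            dz = np.concatenate(
                [
                    di * st["i"] * (1 - st["i"]),
                    df * st["f"] * (1 - st["f"]),
                    do * st["o"] * (1 - st["o"]),
                    dg * (1 - st["g"] ** 2),
                ],
                axis=1,
            )
            g["Wx"] += st["x"].T @ dz
            g["Wh"] += st["h_prev"].T @ dz
            g["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * st["f"]
        return g


class Conv1DNet(_BaseNet):
    """conv1d(neurons//4 filters, width 3) -> act -> global average pool -> softmax."""

    kernel = 3

    def _prepare(self, X):
        return reshape_to_sequence(X)

    def _build(self, input_shape):
        T, d = input_shape
        if T < self.kernel:
            raise TrainingError(f"sequence length {T} shorter than kernel {self.kernel}")
        s = self.settings
        f = max(4, s.neurons // 4)
        self.params = {
            "K": _init((self.kernel * d, f), s.init_mode, self._rng).reshape(self.kernel, d, f),
            "bk": np.zeros(f),
            "Wo": _init((f, self.n_classes), s.init_mode, self._rng),
            "bo": np.zeros(self.n_classes),
        }

    def _patches(self, X):
        B, T, d = X.shape
        L = T - self.kernel + 1
        idx = np.arange(self.kernel)[None, :] + np.arange(L)[:, None]
        return X[:, idx, :]  # [B, L, k, d]

    def _forward(self, X, train):
        P = self._patches(X)
        conv = np.einsum("blkd,kdf->blf", P, self.params["K"]) + self.params["bk"]
        a = _act(conv, self.settings.activation)
        pooled = a.mean(axis=1)
        logits = pooled @ self.params["Wo"] + self.params["bo"]
        return logits, {"P": P, "a": a}

    def _backward(self, c, dlogits):
        g = {}
        pooled = c["a"].mean(axis=1)
        g["Wo"] = pooled.T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        da = (dlogits @ self.params["Wo"].T)[:, None, :] / c["a"].shape[1]
        dconv = da * _act_grad(c["a"], self.settings.activation)
        g["K"] = np.einsum("blkd,blf->kdf", c["P"], dconv)
        g["bk"] = dconv.sum(axis=(0, 1))
        return g
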