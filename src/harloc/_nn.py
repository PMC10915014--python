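"""Small, fully deterministic numpy neural networks for CPU-scale training.

Two classifiers are provided: a single-layer LSTM over short sequences of
feature rows (locomotion branch) and a 1-D convolutional stack over a single
feature vector (localization branch).  Both train with Adam on softmax
cross-entropy, are seeded through ``numpy.random.default_rng`` and therefore
bit-reproducible on CPU, and expose their penultimate activations for hybrid
feature fusion.

The implementations are intentionally minimal: full-batch shapes, no
dropout, no GPU paths.  Gradients are exact (verified against finite
differences in the test suite).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Adam:
    """Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _BaseClassifier:
    params: dict[str, np.ndarray]
    classes_: np.ndarray
    loss_history: list[float]

    def weights_checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def _encode_labels(self, y) -> np.ndarray:
        self.classes_ = np.unique(np.asarray(y))
        index = {c: i for i, c in enumerate(self.classes_)}
        return np.asarray([index[v] for v in np.asarray(y)], dtype=int)


class LSTMClassifier(_BaseClassifier):
    """Single-layer LSTM + softmax over sequences of feature rows.

    Input ``X`` has shape (n_instances, T, d); the last hidden state is the
    penultimate representation.
    """

    def __init__(self, hidden: int = 64, epochs: int = 50, batch_size: int = 32,
                 lr: float = 1e-2, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.params = {}
        self.loss_history = []

    def _init_params(self, d: int, n_classes: int) -> None:
        rng = np.random.default_rng(self.seed)
        H = self.hidden
        self.params = {
            "Wx": _glorot(rng, (d, 4 * H)),
            "Wh": _glorot(rng, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wy": _glorot(rng, (H, n_classes)),
            "by": np.zeros(n_classes),
        }
        # forget-gate bias 1: standard stabilizer for short sequences
        self.params["b"][H:2 * H] = 1.0

    def _forward(self, X: np.ndarray):
        B, T, d = X.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = X[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            o = _sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((h, c, i, f, o, g, c_new))
            h, c = h_new, c_new
        logits = h @ self.params["Wy"] + self.params["by"]
        return logits, h, cache

    def _backward(self, X: np.ndarray, y_idx: np.ndarray, probs: np.ndarray,
                  h_last: np.ndarray, cache) -> dict[str, np.ndarray]:
        B, T, d = X.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wy"] = h_last.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wy"].T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g ** 2)],
                axis=1,
            )
            grads["Wx"] += X[:, t, :].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ Wh.T
            dc = dc * f
        return grads

    def fit(self, X: np.ndarray, y) -> "LSTMClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValidationError("LSTM input must be (n, T, d)")
        y_idx = self._encode_labels(y)
        if len(y_idx) != len(X):
            raise ValidationError("label count differs from instance count")
        self._init_params(X.shape[2], len(self.classes_))
        opt = Adam(self.params, lr=self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(X)
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits, h_last, cache = self._forward(X[idx])
                probs = softmax(logits)
                epoch_loss += cross_entropy(probs, y_idx[idx]) * len(idx)
                grads = self._backward(X[idx], y_idx[idx], probs, h_last, cache)
                opt.step(grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self._forward(np.asarray(X, dtype=float))
        return softmax(logits)

    def penultimate(self, X: np.ndarray) -> np.ndarray:
        _, h_last, _ = self._forward(np.asarray(X, dtype=float))
        return h_last


def _conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution.  X: (B, C, L); W: (F, C, K) -> (B, F, L-K+1)."""
    B, C, L = X.shape
    F, _, K = W.shape
    Lo = L - K + 1
    cols = np.empty((B, Lo, C * K))
    for j in range(Lo):
        cols[:, j, :] = X[:, :, j:j + K].reshape(B, C * K)
    out = cols @ W.reshape(F, C * K).T + b
    return out.transpose(0, 2, 1), cols  # (B, F, Lo)


def _conv1d_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                     x_shape: tuple[int, int, int]):
    B, C, L = x_shape
    F, _, K = W.shape
    Lo = L - K + 1
    d = dout.transpose(0, 2, 1)  # (B, Lo, F)
    dW = np.einsum("bjf,bjk->fk", d, cols).reshape(F, C, K)
    db = d.sum(axis=(0, 1))
    dcols = d @ W.reshape(F, C * K)
    dX = np.zeros(x_shape)
    for j in range(Lo):
        dX[:, :, j:j + K] += dcols[:, j, :].reshape(B, C, K)
    return dX, dW, db


def _maxpool2(X: np.ndarray):
    """Non-overlapping max pool of width 2 along the last axis."""
    B, C, L = X.shape
    Lp = L // 2
    x = X[:, :, :2 * Lp].reshape(B, C, Lp, 2)
    arg = x.argmax(axis=3)
    out = x.max(axis=3)
    return out, arg, L


def _maxpool2_backward(dout: np.ndarray, arg: np.ndarray, L: int):
    B, C, Lp = dout.shape
    dx = np.zeros((B, C, Lp, 2))
    b_i, c_i, p_i = np.meshgrid(np.arange(B), np.arange(C), np.arange(Lp), indexing="ij")
    dx[b_i, c_i, p_i, arg] = dout
    dX = np.zeros((B, C, L))
    dX[:, :, :2 * Lp] = dx.reshape(B, C, 2 * Lp)
    return dX


class CNNClassifier(_BaseClassifier):
    """Two 1-D conv blocks (conv-ReLU-maxpool) + dense ReLU + softmax.

    Operates on a single ordered feature vector per row, shape (n, d); the
    dense hidden layer is the penultimate representation.
    """

    def __init__(self, filters: int = 32, kernel: int = 3, hidden: int = 64,
                 epochs: int = 50, batch_size: int = 32, lr: float = 1e-2,
                 seed: int = 0):
        self.filters = filters
        self.kernel = kernel
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.params = {}
        self.loss_history = []

    def _init_params(self, d: int, n_classes: int) -> None:
        F, K = self.filters, self.kernel
        l1 = d - K + 1
        p1 = l1 // 2
        l2 = p1 - K + 1
        p2 = l2 // 2
        if d < K or l1 < 2 or l2 < 1 or p2 < 1:
            raise ValidationError(
                f"feature dimension {d} too small for kernel {K} conv stack"
            )
        rng = np.random.default_rng(self.seed)
        flat = F * p2
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / K), size=(F, 1, K)),
            "b1": np.zeros(F),
            "W2": rng.normal(0.0, np.sqrt(2.0 / (F * K)), size=(F, F, K)),
            "b2": np.zeros(F),
            "Wd": _glorot(rng, (flat, self.hidden)),
            "bd": np.zeros(self.hidden),
            "Wy": _glorot(rng, (self.hidden, n_classes)),
            "by": np.zeros(n_classes),
        }

    def _forward(self, X: np.ndarray):
        x0 = X[:, None, :]  # (B, 1, d)
        z1, cols1 = _conv1d_forward(x0, self.params["W1"], self.params["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, arg1, l1 = _maxpool2(a1)
        z2, cols2 = _conv1d_forward(p1, self.params["W2"], self.params["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, arg2, l2 = _maxpool2(a2)
        flat = p2.reshape(len(X), -1)
        zd = flat @ self.params["Wd"] + self.params["bd"]
        ad = np.maximum(zd, 0.0)
        logits = ad @ self.params["Wy"] + self.params["by"]
        cache = (x0, cols1, z1, a1, arg1, l1, p1, cols2, z2, a2, arg2, l2, p2, flat, zd, ad)
        return logits, cache

    def _backward(self, y_idx: np.ndarray, probs: np.ndarray, cache):
        (x0, cols1, z1, a1, arg1, l1, p1, cols2, z2, a2, arg2, l2, p2,
         flat, zd, ad) = cache
        B = len(y_idx)
        grads = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        grads["Wy"] = ad.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dad = dlogits @ self.params["Wy"].T
        dzd = dad * (zd > 0)
        grads["Wd"] = flat.T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool2_backward(dp2, arg2, l2)
        dz2 = da2 * (z2 > 0)
        dp1, grads["W2"], grads["b2"] = _conv1d_backward(dz2, cols2, self.params["W2"], p1.shape)
        da1 = _maxpool2_backward(dp1, arg1, l1)
        dz1 = da1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = _conv1d_backward(dz1, cols1, self.params["W1"], x0.shape)
        return grads

    def fit(self, X: np.ndarray, y) -> "CNNClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("CNN input must be (n, d)")
        y_idx = self._encode_labels(y)
        self._init_params(X.shape[1], len(self.classes_))
        opt = Adam(self.params, lr=self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(X)
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits, cache = self._forward(X[idx])
                probs = softmax(logits)
                epoch_loss += cross_entropy(probs, y_idx[idx]) * len(idx)
                grads = self._backward(y_idx[idx], probs, cache)
                opt.step(grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=float))
        return softmax(logits)

    def penultimate(self, X: np.ndarray) -> np.ndarray:
        _, cache = self._forward(np.asarray(X, dtype=float))
        return cache[-1]
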