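"""Minimal CPU sequence-model layers with manual backpropagation.

Implements exactly what the stress classifiers need — LSTM and GRU cells,
a 1-D convolution with global average pooling, dense/batch-norm/dropout
layers, softmax cross-entropy and an Adam optimizer with optional global
gradient-norm clipping. Everything is float64 numpy, single threaded and
deterministic given a seed.

Conventions follow the common recurrent-network formulation: the LSTM
gate order is (input, forget, cell, output), gates use a sigmoid, the
cell/candidate nonlinearity is configurable (tanh by default, relu for
the clipped variant), the forget-gate bias starts at 1, input dropout
uses one mask per sequence shared across time steps, and recurrent
dropout masks the hidden state entering the recurrence.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "Dense",
    "BatchNorm",
    "Dropout",
    "ReLU",
    "LSTM",
    "GRU",
    "Conv1DGap",
    "softmax",
    "SoftmaxCrossEntropy",
    "Sequential",
]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _act(name):
    if name == "tanh":
        return np.tanh, lambda y: 1.0 - y * y          # derivative from output
    if name == "relu":
        return lambda x: np.maximum(x, 0.0), lambda y: (y > 0).astype(float)
    if name == "sigmoid":
        return _sigmoid, lambda y: y * (1.0 - y)
    raise ValueError(f"unknown activation {name!r}")


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7, clipnorm=None):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        if self.clipnorm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if total > self.clipnorm:
                scale = self.clipnorm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads = [self._x.T @ dy, dy.sum(axis=0)]
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    def __init__(self, n, momentum=0.99, eps=1e-3):
        super().__init__()
        self.gamma, self.beta = np.ones(n), np.zeros(n)
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean, self.running_var = np.zeros(n), np.ones(n)

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        xhat, std = self._xhat, self._std
        self.grads = [(dy * xhat).sum(axis=0), dy.sum(axis=0)]
        if not self._training:
            return dy * self.gamma / std
        n = dy.shape[0]
        dxhat = dy * self.gamma
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features) input."""

    def __init__(
        self,
        n_in,
        units,
        rng,
        activation="tanh",
        recurrent_activation="sigmoid",
        dropout=0.0,
        recurrent_dropout=0.0,
        return_sequences=False,
    ):
        super().__init__()
        u = units
        limit = np.sqrt(6.0 / (n_in + 4 * u))
        self.Wx = rng.uniform(-limit, limit, size=(n_in, 4 * u))
        # orthogonal recurrent init, one matrix per gate
        self.Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((u, u)))[0] for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * u)
        self.b[u : 2 * u] = 1.0  # forget-gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.units = u
        self.act, self.dact = _act(activation)
        self.gate, self.dgate = _act(recurrent_activation)
        self.dropout, self.recurrent_dropout = dropout, recurrent_dropout
        self.return_sequences = return_sequences
        self.rng = rng

    def forward(self, X, training=False):
        B, T, D = X.shape
        u = self.units
        mx = np.ones((B, D))
        mh = np.ones((B, u))
        if training and self.dropout > 0:
            mx = (self.rng.random((B, D)) >= self.dropout) / (1 - self.dropout)
        if training and self.recurrent_dropout > 0:
            mh = (self.rng.random((B, u)) >= self.recurrent_dropout) / (
                1 - self.recurrent_dropout
            )
        self._mx, self._mh = mx, mh
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        H = np.empty((B, T, u)) if self.return_sequences else None
        for t in range(T):
            x = X[:, t, :] * mx
            z = x @ self.Wx + (h * mh) @ self.Wh + self.b
            i = self.gate(z[:, :u])
            f = self.gate(z[:, u : 2 * u])
            g = self.act(z[:, 2 * u : 3 * u])
            o = self.gate(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            hc = self.act(c)
            h = o * hc
            self._cache.append((x, h_prev, c_prev, i, f, g, o, c, hc))
            if self.return_sequences:
                H[:, t, :] = h
        self._X_shape = X.shape
        return H if self.return_sequences else h

    def backward(self, dY):
        B, T, D = self._X_shape
        u = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, T, D))
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        for t in reversed(range(T)):
            x, h_prev, c_prev, i, f, g, o, c, hc = self._cache[t]
            dh = dh_next + (dY[:, t, :] if self.return_sequences else 0.0)
            if not self.return_sequences and t == T - 1:
                dh = dh + dY
            do = dh * hc * self.dgate(o)
            dc = dc_next + dh * o * self.dact(hc)
            df = dc * c_prev * self.dgate(f)
            di = dc * g * self.dgate(i)
            dg = dc * i * self.dact(g)
            dc_next = dc * f
            dz = np.concatenate([di, df, dg, do], axis=1)
            dWx += x.T @ dz
            dWh += (h_prev * self._mh).T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = (dz @ self.Wx.T) * self._mx
            dh_next = (dz @ self.Wh.T) * self._mh
        self.grads = [dWx, dWh, db]
        return dX


class GRU(Layer):
    """Single GRU layer returning the last hidden state."""

    def __init__(self, n_in, units, rng):
        super().__init__()
        u = units
        limit = np.sqrt(6.0 / (n_in + 3 * u))
        self.Wx = rng.uniform(-limit, limit, size=(n_in, 3 * u))
        self.Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((u, u)))[0] for _ in range(3)], axis=1
        )
        self.b = np.zeros(3 * u)
        self.params = [self.Wx, self.Wh, self.b]
        self.units = u

    def forward(self, X, training=False):
        B, T, D = X.shape
        u = self.units
        h = np.zeros((B, u))
        self._cache = []
        for t in range(T):
            x = X[:, t, :]
            zx = x @ self.Wx + self.b
            zh = h @ self.Wh
            r = _sigmoid(zx[:, :u] + zh[:, :u])
            zg = _sigmoid(zx[:, u : 2 * u] + zh[:, u : 2 * u])
            n = np.tanh(zx[:, 2 * u :] + r * zh[:, 2 * u :])
            h_prev = h
            h = (1 - zg) * n + zg * h_prev
            self._cache.append((x, h_prev, r, zg, n, zh))
        self._X_shape = X.shape
        return h

    def backward(self, dY):
        B, T, D = self._X_shape
        u = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros((B, T, D))
        dh_next = dY.copy()
        for t in reversed(range(T)):
            x, h_prev, r, zg, n, zh = self._cache[t]
            dh = dh_next
            dzg = dh * (h_prev - n) * zg * (1 - zg)
            dn = dh * (1 - zg) * (1 - n * n)
            dr = dn * zh[:, 2 * u :] * r * (1 - r)
            dzx = np.concatenate([dr, dzg, dn], axis=1)
            dzh = np.concatenate([dr, dzg, dn * r], axis=1)
            dWx += x.T @ dzx
            dWh += h_prev.T @ dzh
            db += dzx.sum(axis=0)
            dX[:, t, :] = dzx @ self.Wx.T
            dh_next = dh * zg + dzh @ self.Wh.T
        self.grads = [dWx, dWh, db]
        return dX


class Conv1DGap(Layer):
    """1-D convolution (same padding, ReLU) + global average pooling."""

    def __init__(self, n_in, filters, kernel, rng):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in * kernel + filters))
        self.W = rng.uniform(-limit, limit, size=(kernel, n_in, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.kernel = kernel

    def _pad(self, X):
        k = self.kernel
        lo, hi = (k - 1) // 2, k // 2
        return np.pad(X, ((0, 0), (lo, hi), (0, 0)))

    def forward(self, X, training=False):
        B, T, D = X.shape
        k = self.kernel
        Xp = self._pad(X)
        z = np.zeros((B, T, self.W.shape[2]))
        for j in range(k):
            z += Xp[:, j : j + T, :] @ self.W[j]
        z += self.b
        self._relu_mask = z > 0
        self._Xp, self._T = Xp, T
        a = np.where(self._relu_mask, z, 0.0)
        return a.mean(axis=1)  # global average pool over time

    def backward(self, dy):
        B = dy.shape[0]
        T, k = self._T, self.kernel
        da = np.broadcast_to(dy[:, None, :] / T, self._relu_mask.shape)
        dz = np.where(self._relu_mask, da, 0.0)
        dW = np.zeros_like(self.W)
        dXp = np.zeros_like(self._Xp)
        for j in range(k):
            dW[j] = np.einsum("btd,btf->df", self._Xp[:, j : j + T, :], dz)
            dXp[:, j : j + T, :] += dz @ self.W[j].T
        self.grads = [dW, dz.sum(axis=(0, 1))]
        lo = (k - 1) // 2
        return dXp[:, lo : lo + T, :]


class SoftmaxCrossEntropy:
    def loss_and_grad(self, logits, y_onehot, sample_weight=None):
        p = softmax(logits)
        n = logits.shape[0]
        eps = 1e-12
        if sample_weight is None:
            loss = -float(np.sum(y_onehot * np.log(p + eps))) / n
            return loss, (p - y_onehot) / n
        w = sample_weight[:, None]
        loss = -float(np.sum(w * y_onehot * np.log(p + eps))) / n
        return loss, w * (p - y_onehot) / n


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def _buffers(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out += [layer.running_mean, layer.running_var]
        return out

    def get_weights(self):
        return [p.copy() for p in self.params + self._buffers()]

    def set_weights(self, weights):
        targets = self.params + self._buffers()
        for i, (p, w) in enumerate(zip(targets, weights)):
            if p.shape == w.shape and p is targets[i]:
                p[...] = w
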