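"""Minimal CPU neural-network engine (numpy).

Implements exactly the pieces the worm/non-worm classifier needs:
3x3 same-padding convolution (im2col + matmul), ReLU, 2x2 max pooling,
batch normalisation, dropout, a fully connected layer, softmax
cross-entropy, and the Adam optimiser.  Layers expose ``forward(x, train)``
and ``backward(dy)``; parameters and gradients are plain float32 arrays.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):  # list of dicts {"value": arr, "grad": arr}
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2d(Layer):
    """3x3, stride 1, padding 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.w, "grad": self.dw}, {"value": self.b, "grad": self.db}]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # cols: (n, h, w, c, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._cols, self._shape = cols, (n, c, h, w)
        wmat = self.w.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, c, h, w = self._shape
        k, pad = self.k, self.k // 2
        dymat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dw[:] = (dymat.T @ self._cols).reshape(self.w.shape)
        self.db[:] = dymat.sum(axis=0)
        dcols = (dymat @ self.w.reshape(self.c_out, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Layer):
    """2x2, stride 2; input spatial dims must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return flat.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._argmax[..., None], dy[..., None], axis=-1)
        return (out.reshape(n, c, h // 2, w // 2, 2, 2)
                   .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [{"value": self.gamma, "grad": self.dgamma},
                {"value": self.beta, "grad": self.dbeta}]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        self.dgamma[:] = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[:] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self._train:
            return dy * g / self._std
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
                ) / self._std


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [{"value": self.w, "grad": self.dw}, {"value": self.b, "grad": self.db}]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_count(self) -> int:
        return int(sum(p["value"].size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]):
        for p, w in zip(self.params(), weights):
            p["value"][:] = w
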