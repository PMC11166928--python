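"""A compact numpy neural-network engine.

Implements exactly the pieces the SNP-image classifier needs — 3x1 valid
convolutions, 3x1 max-pooling, dense layers, ReLU, a softmax cross-entropy
head, and the Adam optimizer — with hand-written backward passes that are
verified against numerical gradients in the test suite.  Tensors are
``(batch, height, width, channels)``; parameters are float32 by default
(float64 available for gradient checking).

All randomness (weight initialization, shuffling) flows through explicit
``numpy.random.Generator`` objects, so training is bit-reproducible in
single-threaded execution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x1",
    "MaxPool3x1",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: parameters live in ``params`` / gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3x1(Layer):
    """2-D convolution with a fixed 3x1 kernel (3 rows x 1 column), valid
    padding, stride 1.  Rows are sequences, so the kernel mixes each sequence
    with its two neighbours at every SNP column independently."""

    KH = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        fan_in = self.KH * c_in
        w = rng.standard_normal((self.KH, c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = [w.astype(dtype), np.zeros(c_out, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        h_out = x.shape[1] - self.KH + 1
        if h_out < 1:
            raise ValueError("input height too small for 3x1 convolution")
        out = np.tensordot(x[:, 0:h_out], w[0], axes=([3], [0]))
        for k in range(1, self.KH):
            out += np.tensordot(x[:, k:k + h_out], w[k], axes=([3], [0]))
        out += b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        w, _ = self.params
        h_out = dout.shape[1]
        dw, db = self.grads
        db[...] = dout.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        for k in range(self.KH):
            dw[k] = np.tensordot(x[:, k:k + h_out], dout, axes=([0, 1, 2], [0, 1, 2]))
            dx[:, k:k + h_out] += np.tensordot(dout, w[k], axes=([3], [1]))
        return dx


class MaxPool3x1(Layer):
    """2-D max pooling with a 3x1 window and the framework-default stride
    equal to the window (rows shrink threefold; trailing rows that do not
    fill a window are dropped)."""

    PH = 3

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h_out = h // self.PH
        if h_out < 1:
            raise ValueError("input height too small for 3x1 pooling")
        self._in_shape = x.shape
        xv = x[:, : self.PH * h_out].reshape(n, h_out, self.PH, w, c)
        self._argmax = xv.argmax(axis=2)
        return xv.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h_out = dout.shape[1]
        dxv = np.zeros((n, h_out, self.PH, w, c), dtype=dout.dtype)
        np.put_along_axis(dxv, self._argmax[:, :, None], dout[:, :, None], axis=2)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : self.PH * h_out] = dxv.reshape(n, self.PH * h_out, w, c)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, relu_fan: bool = True):
        super().__init__()
        scale = np.sqrt((2.0 if relu_fan else 1.0) / d_in)
        w = rng.standard_normal((d_in, d_out)) * scale
        self.params = [w.astype(dtype), np.zeros(d_out, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and the gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(logits.dtype), probs


class Adam:
    """Adam with the standard defaults (lr 1e-3, beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
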