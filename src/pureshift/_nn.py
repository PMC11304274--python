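"""Minimal 1-D convolutional network engine in NumPy.

Layers operate on channels-last arrays of shape (batch, length, channels);
that layout lets a stride-1 'same' convolution run as K shifted GEMM calls
on contiguous views, with no im2col copy, so the heavy arithmetic stays in
BLAS.  Gradients are hand-derived and verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "LeakyReLU",
    "Dropout",
    "SEGate",
    "Sequential",
    "Residual",
    "Adam",
]


class Layer:
    """Base class: parameterized differentiable map on (B, N, C) arrays."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        """Learnable arrays by name (views, not copies)."""
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state (running statistics)."""
        return {}


class Conv1d(Layer):
    """Stride-1 'same'-padded 1-D convolution (cross-correlation).

    Weights are stored as (k, c_in, c_out) with odd k so the output length
    equals the input length exactly.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for exact 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        # He / fan-in variance scaling
        std = np.sqrt(2.0 / (c_in * k))
        self.w = rng.normal(0.0, std, size=(k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, n, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.zeros((b, n + 2 * p, c), dtype=self.w.dtype)
        xp[:, p:p + n] = x
        out = np.empty((b, n, self.c_out), dtype=self.w.dtype)
        out[...] = self.b
        for k in range(self.k):
            out += xp[:, k:k + n] @ self.w[k]
        self._xp = xp
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        b, n, _ = grad.shape
        p = self.k // 2
        self.db[...] = grad.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for k in range(self.k):
            xv = xp[:, k:k + n]
            self.dw[k] = np.matmul(xv.transpose(0, 2, 1), grad).sum(axis=0)
            dxp[:, k:k + n] += grad @ self.w[k].T
        self._xp = None
        return dxp[:, p:p + n]

    def parameters(self):
        return {"w": self.w, "b": self.b}

    def gradients(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) with affine pair;
    inference uses exponential running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 1))
        self.dbeta[...] = grad.sum(axis=(0, 1))
        gg = grad * self.gamma
        dx = (inv / m) * (
            m * gg
            - gg.sum(axis=(0, 1), keepdims=True)
            - xhat * (gg * xhat).sum(axis=(0, 1), keepdims=True)
        )
        self._cache = None
        return dx.astype(grad.dtype, copy=False)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, x * x.dtype.type(self.slope))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, grad, grad * grad.dtype.type(self.slope))
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(
            x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class SEGate(Layer):
    """Squeeze-and-excitation channel attention.

    Global average pool over length -> bottleneck dense (C -> C/r) -> ReLU ->
    dense (C/r -> C) -> sigmoid; each channel is rescaled by its gate scalar,
    which lies strictly inside (0, 1).
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator,
                 dtype=np.float32):
        if c % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channels {c}")
        h = c // reduction
        self.c, self.h = c, h
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / c), size=(h, c)).astype(dtype)
        self.b1 = np.zeros(h, dtype=dtype)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / h), size=(c, h)).astype(dtype)
        self.b2 = np.zeros(c, dtype=dtype)
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)
        self._cache = None

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Per-channel attention scalars for (B, N, C) input; shape (B, C)."""
        z = x.mean(axis=1)
        a = np.maximum(z @ self.w1.T + self.b1, 0.0)
        return 1.0 / (1.0 + np.exp(-(a @ self.w2.T + self.b2)))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x.mean(axis=1)
        pre1 = z @ self.w1.T + self.b1
        a = np.maximum(pre1, 0.0)
        s = 1.0 / (1.0 + np.exp(-(a @ self.w2.T + self.b2)))
        self._cache = (x, z, pre1, a, s)
        return x * s[:, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, pre1, a, s = self._cache
        n = x.shape[1]
        dx = grad * s[:, None, :]
        ds = (grad * x).sum(axis=1)            # (B, C)
        dpre2 = ds * s * (1.0 - s)
        self.dw2[...] = dpre2.T @ a
        self.db2[...] = dpre2.sum(axis=0)
        da = dpre2 @ self.w2
        dpre1 = da * (pre1 > 0)
        self.dw1[...] = dpre1.T @ z
        self.db1[...] = dpre1.sum(axis=0)
        dz = dpre1 @ self.w1                    # (B, C)
        dx += dz[:, None, :] / n
        self._cache = None
        return dx

    def parameters(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def gradients(self):
        return {"w1": self.dw1, "b1": self.db1, "w2": self.dw2, "b2": self.db2}


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Layer):
    """y = x + body(x); identity skip requires matching channel counts."""

    def __init__(self, body: Layer):
        self.body = body

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x + self.body.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.body.backward(grad)


def iter_layers(layer: Layer):
    """Depth-first iteration over leaf layers."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    elif isinstance(layer, Residual):
        yield from iter_layers(layer.body)
    else:
        yield layer


def named_parameters(root: Layer) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, leaf in enumerate(iter_layers(root)):
        for name, arr in leaf.parameters().items():
            out[f"{i}.{leaf.__class__.__name__}.{name}"] = arr
    return out


def named_buffers(root: Layer) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, leaf in enumerate(iter_layers(root)):
        for name, arr in leaf.buffers().items():
            out[f"{i}.{leaf.__class__.__name__}.{name}"] = arr
    return out


class Adam:
    """Adaptive-moment gradient descent on a layer tree's parameters."""

    def __init__(self, root: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.leaves = [leaf for leaf in iter_layers(root) if leaf.parameters()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in leaf.parameters().items()}
            for leaf in self.leaves
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in leaf.parameters().items()}
            for leaf in self.leaves
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for leaf, m, v in zip(self.leaves, self.m, self.v):
            params = leaf.parameters()
            grads = leaf.gradients()
            for k in params:
                g = grads[k]
                m[k][...] = b1 * m[k] + (1 - b1) * g
                v[k][...] = b2 * v[k] + (1 - b2) * g * g
                params[k][...] -= self.lr * (m[k] / bias1) / (
                    np.sqrt(v[k] / bias2) + self.eps
                )
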