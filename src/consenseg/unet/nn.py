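"""Minimal numpy neural-network primitives for the segmentation U-Net.

Implements exactly the layers the architecture needs — unpadded 3x3
convolution, leaky ReLU, 2x2 max-pooling, 2x2 stride-2 transposed
convolution, batch normalization, 1x1 convolution — each with an explicit
backward pass, plus the Adam optimizer.  Data layout is ``(N, C, H, W)``
float32; convolutions are evaluated as nine shifted channel-contractions,
which keeps memory linear in the activation size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "LeakyReLU",
    "MaxPool2",
    "UpConv2x2",
    "BatchNorm",
    "Adam",
    "truncated_normal",
]


def truncated_normal(
    rng: np.random.Generator, shape: tuple[int, ...], std: float, bound: float = 2.0
) -> np.ndarray:
    """Normal(0, std) truncated at +-bound*std, by resampling."""
    x = rng.standard_normal(shape)
    bad = np.abs(x) > bound
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > bound
    return (x * std).astype(np.float32)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Conv3x3(Layer):
    """Unpadded (valid) 3x3 convolution; He-scaled truncated-normal init."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (cin * 9))
        self.params = {
            "W": truncated_normal(rng, (3, 3, cin, cout), std),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        n, cin, h, w = x.shape
        ho, wo = h - 2, w - 2
        out = np.zeros((n, ho, wo, W.shape[3]), dtype=np.result_type(x, W))
        for i in range(3):
            for j in range(3):
                sl = x[:, :, i : i + ho, j : j + wo]
                out += np.tensordot(sl, W[i, j], axes=([1], [0]))
        out += b
        if train:
            self._x = x
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        W = self.params["W"]
        n, cout, ho, wo = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                sl = x[:, :, i : i + ho, j : j + wo]
                dW[i, j] = np.tensordot(sl, dyt, axes=([0, 2, 3], [0, 1, 2]))
                dx[:, :, i : i + ho, j : j + wo] += np.tensordot(
                    dyt, W[i, j], axes=([3], [1])
                ).transpose(0, 3, 1, 2)
        self.grads = {"W": dW, "b": dyt.sum(axis=(0, 1, 2))}
        self._x = None
        return dx


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / cin)
        self.params = {
            "W": truncated_normal(rng, (cin, cout), std),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.tensordot(x, self.params["W"], axes=([1], [0])) + self.params["b"]
        if train:
            self._x = x
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        dyt = dy.transpose(0, 2, 3, 1)
        self.grads = {
            "W": np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2])),
            "b": dyt.sum(axis=(0, 1, 2)),
        }
        self._x = None
        return np.ascontiguousarray(
            np.tensordot(dyt, self.params["W"], axes=([3], [1])).transpose(0, 3, 1, 2)
        )


class LeakyReLU(Layer):
    def __init__(self, leak: float = 0.1):
        super().__init__()
        self.leak = leak
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.leak * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, self.leak * dy)
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (input H, W must be even)."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        grid = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(grid, self._idx[..., None], dy[..., None], axis=-1)
        dx = (
            grid.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = self._shape = None
        return dx


class UpConv2x2(Layer):
    """Transposed convolution, kernel 2x2, stride 2 (non-overlapping)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / cin)
        self.params = {
            "W": truncated_normal(rng, (2, 2, cin, cout), std),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        n, cin, h, w = x.shape
        cout = W.shape[3]
        out = np.empty((n, cout, 2 * h, 2 * w), dtype=np.result_type(x, W))
        for i in range(2):
            for j in range(2):
                out[:, :, i::2, j::2] = (
                    np.tensordot(x, W[i, j], axes=([1], [0])) + b
                ).transpose(0, 3, 1, 2)
        if train:
            self._x = x
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                d = np.ascontiguousarray(dy[:, :, i::2, j::2].transpose(0, 2, 3, 1))
                dW[i, j] = np.tensordot(x, d, axes=([0, 2, 3], [0, 1, 2]))
                db += d.sum(axis=(0, 1, 2))
                dx += np.tensordot(d, W[i, j], axes=([3], [1])).transpose(0, 3, 1, 2)
        self.grads = {"W": dW, "b": db}
        self._x = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W), with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return g * xhat + b
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        dx = (
            inv[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            )
        )
        self.grads = {"gamma": dgamma, "beta": dbeta}
        self._cache = None
        return dx


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, lr: float = 4e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
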