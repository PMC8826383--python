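"""Minimal NumPy layers for 1D sequence models.

Tensor layout is (batch, length, channels), float32. Each layer implements
``forward(x, training)`` and ``backward(dout)``; learnable arrays live in
``.params`` with matching ``.grads``. Convolutions are realised as
im2col + GEMM so the heavy lifting stays in BLAS.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def conv1d_feature_map(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-region sliding dot product at stride 1.

    Z_n = sum_j x[(n-1)+j] * k[j] with 1-based n, i.e. output length
    len(x) - len(kernel) + 1. Reference form of the convolution the Conv1D
    layer computes per channel pair.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    n, k = x.shape[0], kernel.shape[0]
    if k > n:
        raise ValueError("kernel longer than input")
    out = np.empty(n - k + 1)
    for i in range(n - k + 1):
        out[i] = float(np.dot(x[i : i + k], kernel))
    return out


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1D(Layer):
    """Stride-1 1D convolution with 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel_size
        self.c_in = c_in
        self.c_out = c_out
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size - 1 - self.pad_left
        self.params["W"] = _he_init(rng, (kernel_size * c_in, c_out), kernel_size * c_in)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, xp: np.ndarray, L: int) -> np.ndarray:
        B, _, C = xp.shape
        cols = np.empty((B, L, self.k * C), dtype=DTYPE)
        for j in range(self.k):
            cols[:, :, j * C : (j + 1) * C] = xp[:, j : j + L, :]
        return cols

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        xp = np.zeros((B, L + self.k - 1, C), dtype=DTYPE)
        xp[:, self.pad_left : self.pad_left + L, :] = x
        cols = self._im2col(xp, L)
        self._cache = (cols, (B, L, C))
        out = cols.reshape(B * L, -1) @ self.params["W"]
        return out.reshape(B, L, self.c_out) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, L, C) = self._cache
        d2 = dout.reshape(B * L, self.c_out).astype(DTYPE)
        self.grads["W"] = cols.reshape(B * L, -1).T @ d2
        self.grads["b"] = d2.sum(axis=0)
        dcols = (d2 @ self.params["W"].T).reshape(B, L, self.k * C)
        dxp = np.zeros((B, L + self.k - 1, C), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, j : j + L, :] += dcols[:, :, j * C : (j + 1) * C]
        return dxp[:, self.pad_left : self.pad_left + L, :]


class LocallyConnected1D(Layer):
    """Convolution-shaped layer with untied (per-position) filters, valid padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, l_in: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel_size
        self.c_in = c_in
        self.c_out = c_out
        self.l_out = l_in - kernel_size + 1
        if self.l_out < 1:
            raise ValueError("input shorter than kernel")
        self.params["W"] = _he_init(
            rng, (self.l_out, kernel_size * c_in, c_out), kernel_size * c_in
        )
        self.params["b"] = np.zeros((self.l_out, c_out), dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        cols = np.empty((B, self.l_out, self.k * C), dtype=DTYPE)
        for j in range(self.k):
            cols[:, :, j * C : (j + 1) * C] = x[:, j : j + self.l_out, :]
        self._cache = (cols, (B, L, C))
        return np.einsum("blk,lko->blo", cols, self.params["W"], optimize=True) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, L, C) = self._cache
        dout = dout.astype(DTYPE)
        self.grads["W"] = np.einsum("blk,blo->lko", cols, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=0)
        dcols = np.einsum("blo,lko->blk", dout, self.params["W"], optimize=True)
        dx = np.zeros((B, L, C), dtype=DTYPE)
        for j in range(self.k):
            dx[:, j : j + self.l_out, :] += dcols[:, :, j * C : (j + 1) * C]
        return dx

    def set_tied_kernel(self, W: np.ndarray, b: np.ndarray) -> None:
        """Set every position's kernel to the same values (plain-conv equivalence)."""
        self.params["W"][:] = W[None, :, :]
        self.params["b"][:] = b[None, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(DTYPE), x.shape[0] * x.shape[1])
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1)).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=(0, 1)).astype(DTYPE)
        g = self.params["gamma"]
        dxhat = dout * g
        dx = (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * (dxhat * xhat).mean(axis=(0, 1))
        ) * inv
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(DTYPE)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder position is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, L, C = x.shape
        L_out = L // self.pool
        xr = x[:, : L_out * self.pool, :].reshape(B, L_out, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (B, L, C)
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._shape
        L_out = L // self.pool
        dxr = np.zeros((B, L_out, self.pool, C), dtype=DTYPE)
        bi, li, ci = np.ogrid[:B, :L_out, :C]
        dxr[bi, li, self._argmax, ci] = dout
        dx = np.zeros((B, L, C), dtype=DTYPE)
        dx[:, : L_out * self.pool, :] = dxr.reshape(B, L_out * self.pool, C)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, None, :], self._L, axis=1) / self._L


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _he_init(rng, (n_in, n_out), n_in)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(DTYPE)
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def all_layers(self) -> list[Layer]:
        return self.layers


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=DTYPE)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


SCORE_CLIP = 1e-7


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean binary cross-entropy; scores are clipped away from {0, 1}."""
    y = np.asarray(y, dtype=float)
    yhat = np.clip(np.asarray(yhat, dtype=float), SCORE_CLIP, 1.0 - SCORE_CLIP)
    if y.size == 0:
        raise ValueError("empty batch")
    if y.shape != yhat.shape:
        raise ValueError("labels and scores must align")
    return float(-np.mean(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)))


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 0.00125, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [ly for ly in layers if ly.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, ly in enumerate(self.layers):
            for k, p in ly.params.items():
                g = ly.grads[k]
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * g
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
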