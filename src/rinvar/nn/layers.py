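"""Minimal 2D-CNN layer library with manual backpropagation.

All layers follow the same contract: ``forward(x, training)`` caches what the
backward pass needs, ``backward(dout)`` returns the gradient with respect to
the input and fills ``self.grads`` (keyed like ``self.params``).  Tensors are
channels-last ``(N, H, W, C)`` float64 arrays; float64 keeps the training loop
bit-reproducible across runs on the same platform.

Only what the residual-network classifier needs is implemented: convolution
(im2col), batch normalization, LeakyReLU, 3x3 max pooling, global average
pooling and a dense head.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "LeakyReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: parameter-free identity layer."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """TF-style 'same' padding: output ceil(n/s), asymmetric pad if odd."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    lo = total // 2
    return out, lo, total - lo


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int, oh: int, ow: int) -> np.ndarray:
    """Extract strided (kh, kw) patches from padded input (N,Hp,Wp,C)."""
    n, _, _, c = xp.shape
    cols = np.empty((n, oh, ow, kh, kw, c), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i : i + s * oh : s, j : j + s * ow : s, :]
    return cols


def _col2im(dcols: np.ndarray, shape: tuple, kh: int, kw: int, s: int) -> np.ndarray:
    """Scatter-add patch gradients back onto the padded input."""
    n, oh, ow = dcols.shape[:3]
    dxp = np.zeros(shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcols[:, :, :, i, j, :]
    return dxp


class Conv2D(Layer):
    """2D convolution, 'same' padding, He-normal init, optional bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.params["W"] = w
        if bias:
            self.params["b"] = np.zeros(c_out)
        self.kernel, self.stride, self.use_bias = kernel, stride, bias

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        oh, ph_lo, ph_hi = _same_pad(h, k, s)
        ow, pw_lo, pw_hi = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (ph_lo, ph_hi), (pw_lo, pw_hi), (0, 0)))
        cols = _im2col(xp, k, k, s, oh, ow)
        flat = cols.reshape(n * oh * ow, -1)
        wm = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        out = flat @ wm
        if self.use_bias:
            out += self.params["b"]
        self._cache = (flat, xp.shape, (ph_lo, pw_lo), x.shape, oh, ow)
        return out.reshape(n, oh, ow, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat, xp_shape, (ph_lo, pw_lo), x_shape, oh, ow = self._cache
        k, s = self.kernel, self.stride
        n = dout.shape[0]
        dflat_out = dout.reshape(n * oh * ow, -1)
        wshape = self.params["W"].shape
        self.grads["W"] = (flat.T @ dflat_out).reshape(wshape)
        if self.use_bias:
            self.grads["b"] = dflat_out.sum(axis=0)
        wm = self.params["W"].reshape(-1, wshape[-1])
        dcols = (dflat_out @ wm.T).reshape(n, oh, ow, k, k, wshape[2])
        dxp = _col2im(dcols, xp_shape, k, k, s)
        h, w = x_shape[1], x_shape[2]
        return dxp[:, ph_lo : ph_lo + h, pw_lo : pw_lo + w, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        # standard batch-norm backward (batch statistics)
        return inv / m * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.alpha * dout, dout)


class MaxPool2D(Layer):
    """Max pooling with 'same' padding (padded entries are -inf)."""

    def __init__(self, pool: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.pool, self.stride = pool, stride

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s = self.pool, self.stride
        n, h, w, c = x.shape
        oh, ph_lo, ph_hi = _same_pad(h, k, s)
        ow, pw_lo, pw_hi = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (ph_lo, ph_hi), (pw_lo, pw_hi), (0, 0)),
                    constant_values=-np.inf)
        cols = _im2col(xp, k, k, s, oh, ow).reshape(n, oh, ow, k * k, c)
        self._idx = cols.argmax(axis=3)
        self._geom = (xp.shape, ph_lo, pw_lo, (n, h, w, c), oh, ow)
        return cols.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp_shape, ph_lo, pw_lo, x_shape, oh, ow = self._geom
        k, s = self.pool, self.stride
        n, h, w, c = x_shape
        onehot = self._idx[..., None, :] == np.arange(k * k)[:, None]
        dcols = (dout[..., None, :] * onehot).reshape(n, oh, ow, k, k, c)
        dxp = _col2im(dcols, xp_shape, k, k, s)
        return dxp[:, ph_lo : ph_lo + h, pw_lo : pw_lo + w, :]


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.

    ``labels`` are integer class indices.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
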