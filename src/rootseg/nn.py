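"""Minimal NumPy layers for convolutional encoder-decoder networks.

Implements exactly the pieces the root-segmentation network needs: valid
(unpadded) 3x3 convolution, 2x2 max-pooling, 2x2 stride-2 up-convolution,
ReLU, group normalization, and SGD with Nesterov momentum and weight decay.
Forward passes cache what the analytic backward passes require; convolutions
are lowered to matrix products (im2col) so the heavy lifting runs in BLAS.

Arrays are float32, layout (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "ConvValid",
    "UpConv2x2",
    "MaxPool2",
    "ReLU",
    "GroupNorm",
    "SGDNesterov",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He (Kaiming) normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Param:
    """A trainable array with its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix for a k x k window."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, ho, wo)


class ConvValid:
    """k x k convolution with no padding (output shrinks by k-1 per side pair)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.w = Param(he_normal(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cols = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.k
        cols, (n, ho, wo) = _im2col(x, k)
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T
        out += self.b.value
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        n, oc, ho, wo = dout.shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(-1, oc))
        self.w.grad = (dmat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad = dmat.sum(axis=0)
        self._cols = None
        # dX: correlate the (k-1)-padded output gradient with flipped kernels.
        p = k - 1
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        cols2, (n2, h2, w2) = _im2col(dp, k)
        wr = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, -1)
        dx = (cols2 @ wr.T).reshape(n2, h2, w2, self.in_ch).transpose(0, 3, 1, 2)
        assert dx.shape == self._in_shape
        return np.ascontiguousarray(dx)

    def params(self):
        return [self.w, self.b]


class UpConv2x2:
    """Learned 2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        # weight layout (in, out, 2, 2)
        self.w = Param(he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._xmat = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xmat = np.ascontiguousarray(x.transpose(0, 2, 3, 1).reshape(n * h * w, c))
        y = xmat @ self.w.value.reshape(self.in_ch, -1)  # (N*H*W, out*4)
        y = y.reshape(n, h, w, self.out_ch, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w).copy()
        y += self.b.value[None, :, None, None]
        if train:
            self._xmat = xmat
            self._in_shape = x.shape
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, oc, h2, w2 = dout.shape
        h, w = h2 // 2, w2 // 2
        d = dout.reshape(n, oc, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        d = np.ascontiguousarray(d.reshape(n * h * w, oc * 4))
        self.w.grad = (self._xmat.T @ d).reshape(self.w.value.shape)
        self.b.grad = dout.sum(axis=(0, 2, 3))
        dx = d @ self.w.value.reshape(self.in_ch, -1).T
        self._xmat = None
        return np.ascontiguousarray(dx.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2))

    def params(self):
        return [self.w, self.b]


class MaxPool2:
    """2x2 max pooling with stride 2; input sides must be even."""

    def __init__(self):
        self._idx = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool input sides must be even, got {h}x{w}")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dv, self._idx[..., None], dout[..., None], axis=-1)
        dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dv.reshape(n, c, h, w))

    def params(self):
        return []


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(x.dtype, copy=False)
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, 0.0)
        self._mask = None
        return dx

    def params(self):
        return []


class GroupNorm:
    """Group normalization over channel groups (batch-size independent)."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(n, c, h, w).astype(np.float32, copy=False)
        if train:
            self._cache = (xhat, inv, (n, c, h, w))
        return xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, (n, c, h, w) = self._cache
        g = self.groups
        self.gamma.grad = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad = dout.sum(axis=(0, 2, 3))
        dxhat = (dout * self.gamma.value[None, :, None, None]).reshape(n, g, -1)
        xh = xhat.reshape(n, g, -1)
        m = dxhat.shape[2]
        s1 = dxhat.sum(axis=2, keepdims=True)
        s2 = (dxhat * xh).sum(axis=2, keepdims=True)
        dx = (inv / m) * (m * dxhat - s1 - xh * s2)
        self._cache = None
        return dx.reshape(n, c, h, w).astype(np.float32, copy=False)

    def params(self):
        return [self.gamma, self.beta]


class SGDNesterov:
    """SGD with Nesterov momentum and (decoupled-from-nothing) L2 weight decay.

    Update per parameter p with gradient g:
        g <- g + weight_decay * p
        v <- momentum * v + g
        p <- p - lr * (g + momentum * v)
    """

    def __init__(self, params: list, momentum: float = 0.99, weight_decay: float = 1e-5):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        mu, wd = self.momentum, self.weight_decay
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if wd:
                g = g + wd * p.value
            v *= mu
            v += g
            p.value -= lr * (g + mu * v)
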