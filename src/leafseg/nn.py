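"""Minimal CNN building blocks with explicit reverse-mode gradients.

All tensors are NHWC ``float32`` numpy arrays. Every layer caches what its
backward pass needs on ``forward(..., train=True)``; calling ``backward``
accumulates parameter gradients in place and returns the gradient with
respect to the layer input. Initialisation draws from a caller-supplied
``numpy.random.Generator`` so models are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2d",
    "ConvTranspose2d",
    "Dense",
    "ResidualConvBlock",
    "Adam",
    "sigmoid",
    "softmax",
]


class Param:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def _he_std(fan_in: int) -> float:
    # He initialisation; the small leak barely changes the optimal gain.
    return float(np.sqrt(2.0 / fan_in))


class Conv2d:
    """k x k convolution, stride 1, zero 'same' padding, NHWC layout.

    Implemented as a sum of per-offset matrix products (one (..., cin) @
    (cin, cout) matmul per kernel tap), which avoids materialising an
    im2col buffer.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.k = k
        self.pad = (k - 1) // 2
        w = rng.normal(0.0, _he_std(k * k * cin), size=(k, k, cin, cout))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.empty((b, h, w, self.cout), dtype=x.dtype)
        y[...] = self.b.v
        for i in range(k):
            for j in range(k):
                np.add(y, xp[:, i:i + h, j:j + w, :] @ self.w.v[i, j],
                       out=y)
        if train:
            self._cache = (xp, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        b, h, w, c = xshape
        k, p = self.k, self.pad
        dyf = dy.reshape(-1, self.cout)
        self.b.g += dyf.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i:i + h, j:j + w, :].reshape(-1, c)
                self.w.g[i, j] += sl.T @ dyf
                dxp[:, i:i + h, j:j + w, :] += dy @ self.w.v[i, j].T
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            xf = x.reshape(-1, x.shape[-1])
            n = xf.shape[0]
            mu = xf.mean(axis=0)
            var = np.einsum("nc,nc->c", xf, xf, optimize=True) / n - mu * mu
            np.maximum(var, 0.0, out=var)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma.v * xhat + self.beta.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dgamma = (dy * xhat).sum(axis=(0, 1, 2))
        dbeta = dy.sum(axis=(0, 1, 2))
        self.gamma.g += dgamma
        self.beta.g += dbeta
        return (self.gamma.v * inv) * (dy - dbeta / m - xhat * dgamma / m)


class LeakyReLU:
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2d:
    """2x2 max pooling, stride 2. Input spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        b, h, w, c = xshape
        dxr = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(b, h, w, c)


class ConvTranspose2d:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, _he_std(cin), size=(cin, 2, 2, cout))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, _ = x.shape
        y = np.einsum("bhwc,cpqo->bhpwqo", x, self.w.v, optimize=True)
        y = y.reshape(b, 2 * h, 2 * w, self.cout) + self.b.v
        if train:
            self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        b, h, w, _ = x.shape
        dyr = dy.reshape(b, h, 2, w, 2, self.cout)
        self.w.g += np.einsum("bhwc,bhpwqo->cpqo", x, dyr, optimize=True)
        self.b.g += dy.sum(axis=(0, 1, 2))
        return np.einsum("bhpwqo,cpqo->bhwc", dyr, self.w.v, optimize=True)


class Dense:
    """Fully connected layer over flattened input (the 'final SxS conv')."""

    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, _he_std(nin), size=(nin, nout))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(nout, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xf = x.reshape(x.shape[0], -1)
        if train:
            self._cache = (xf, x.shape)
        return xf @ self.w.v + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, xshape = self._cache
        self.w.g += xf.T @ dy
        self.b.g += dy.sum(axis=0)
        return (dy @ self.w.v.T).reshape(xshape)


class ResidualConvBlock:
    """Three 3x3 conv+BN+LeakyReLU layers with identity adds between them.

    The first convolution changes the channel width; the two following
    convolutions keep it and add their input back (residual connections
    within the block).
    """

    def __init__(self, cin: int, width: int, rng: np.random.Generator,
                 slope: float = 0.1, dtype=np.float32):
        self.conv = [Conv2d(cin, width, 3, rng, dtype),
                     Conv2d(width, width, 3, rng, dtype),
                     Conv2d(width, width, 3, rng, dtype)]
        self.bn = [BatchNorm2d(width, dtype=dtype) for _ in range(3)]
        self.act = [LeakyReLU(slope) for _ in range(3)]

    def params(self):
        out = []
        for c, b in zip(self.conv, self.bn):
            out += c.params() + b.params()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.act[0].forward(
            self.bn[0].forward(self.conv[0].forward(x, train), train), train)
        for i in (1, 2):
            z = self.act[i].forward(
                self.bn[i].forward(self.conv[i].forward(y, train), train),
                train)
            y = z + y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i in (2, 1):
            dz = self.act[i].backward(dy)
            dz = self.bn[i].backward(dz)
            dy = dy + self.conv[i].backward(dz)
        dz = self.act[0].backward(dy)
        dz = self.bn[0].backward(dz)
        return self.conv[0].backward(dz)


class Adam:
    def __init__(self, params, lr: float = 1e-3, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.g - m)
            v += (1.0 - self.b2) * (p.g * p.g - v)
            p.v -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def clip_global_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.g ** 2).sum()) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for p in params:
            p.g *= scale
    return total


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)
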