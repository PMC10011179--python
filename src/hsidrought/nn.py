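"""Minimal feed-forward CNN core in numpy.

Implements exactly the layers needed by the LeNet-5 image-feature
extractor and the one-block 1-D DenseNet classifier: 2-D/1-D valid or
padded convolution (im2col), 2x2 average pooling, dense layers, ReLU,
global average pooling, softmax cross-entropy and an Adam optimizer.
Forward and backward passes are hand-written; all randomness flows
through an explicit ``numpy.random.Generator`` so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Conv1d",
    "AvgPool2d",
    "Dense",
    "ReLU",
    "Flatten",
    "GlobalAvgPool1d",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


class Layer:
    """Base class: layers expose params/grads as parallel lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col2d(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, Ho*Wo) for stride-1 valid convolution."""
    n, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, kh, kw, ho, wo), strides=(s0, s1, s2, s3, s2, s3)
    )
    return view.reshape(n, c * kh * kw, ho * wo)


def _col2im2d(cols: np.ndarray, x_shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col2d` (scatter-add)."""
    n, c, h, w = x_shape
    ho, wo = h - kh + 1, w - kw + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    x = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + ho, j : j + wo] += cols[:, :, i, j]
    return x


class Conv2d(Layer):
    """Stride-1 valid 2-D convolution (cross-correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        self.W = _he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col2d(x, self.kernel, self.kernel)
        n = x.shape[0]
        ho = x.shape[2] - self.kernel + 1
        wo = x.shape[3] - self.kernel + 1
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.einsum("of,nfl->nol", wmat, self._cols) + self.b[None, :, None]
        return out.reshape(n, -1, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        gflat = grad.reshape(n, grad.shape[1], -1)
        self.grads[0][...] = np.einsum("nol,nfl->of", gflat, self._cols).reshape(self.W.shape)
        self.grads[1][...] = gflat.sum(axis=(0, 2))
        wmat = self.W.reshape(self.W.shape[0], -1)
        dcols = np.einsum("of,nol->nfl", wmat, gflat)
        return _col2im2d(dcols, self._x_shape, self.kernel, self.kernel)


class Conv1d(Layer):
    """Stride-1 1-D convolution with symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        pad: int = 0,
    ):
        super().__init__()
        self.kernel = kernel
        self.pad = pad
        fan_in = in_channels * kernel
        self.W = _he_init(rng, (out_channels, in_channels, kernel), fan_in)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp_shape = x.shape
        n, c, l = x.shape
        lo = l - self.kernel + 1
        s0, s1, s2 = x.strides
        view = np.lib.stride_tricks.as_strided(
            x, shape=(n, c, self.kernel, lo), strides=(s0, s1, s2, s2)
        )
        self._cols = view.reshape(n, c * self.kernel, lo)
        wmat = self.W.reshape(self.W.shape[0], -1)
        return np.einsum("of,nfl->nol", wmat, self._cols) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.einsum("nol,nfl->of", grad, self._cols).reshape(self.W.shape)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        wmat = self.W.reshape(self.W.shape[0], -1)
        dcols = np.einsum("of,nol->nfl", wmat, grad)
        n, c, l = self._xp_shape
        lo = l - self.kernel + 1
        dcols = dcols.reshape(n, c, self.kernel, lo)
        dx = np.zeros(self._xp_shape, dtype=grad.dtype)
        for i in range(self.kernel):
            dx[:, :, i : i + lo] += dcols[:, :, i]
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad]
        return dx


class AvgPool2d(Layer):
    """Non-overlapping 2x2 (or kxk) average pooling."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.k
        g = grad[:, :, :, None, :, None] / (k * k)
        g = np.broadcast_to(g, grad.shape[:2] + (grad.shape[2], k, grad.shape[3], k))
        return g.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class GlobalAvgPool1d(Layer):
    """(N, C, L) -> (N, C) mean over the length axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l = self._in_shape
        return np.broadcast_to(grad[:, :, None] / l, self._in_shape).copy()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m[...] = self.beta1 * m + (1 - self.beta1) * g
                v[...] = self.beta2 * v + (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
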