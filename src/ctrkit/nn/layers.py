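"""Layers with explicit forward/backward passes.

Tensors are ``(N, C, H, W)`` float arrays.  Each layer caches what its
backward pass needs during forward; ``backward`` consumes the upstream
gradient and accumulates parameter gradients in-place (``zero_grad`` resets
them).  Convolution gradients w.r.t. the input are computed as a correlation
of the upstream gradient with the 180°-rotated kernels — the same im2col
machinery as forward, which keeps everything inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params(self) -> list[dict]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p["grad"][...] = 0.0


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H_out*W_out, C*k*k) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N, C, Ho, Wo, k, k
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, ho, wo)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding by default (k odd)."""

    def __init__(self, cin: int, cout: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialisation for ReLU nets
        self.W = rng.normal(0.0, scale, size=(cout, cin * k * k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def params(self):
        return [
            {"name": "W", "value": self.W, "grad": self.gW},
            {"name": "b", "value": self.b, "grad": self.gb},
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (n, ho, wo) = _im2col(x, self.k, self.pad)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W.T + self.b
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, co, ho, wo = g.shape
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.gW += gm.T @ self._cols
        self.gb += gm.sum(axis=0)
        # dX: correlate g (padded with k-1-pad) against flipped kernels.
        Wk = self.W.reshape(co, self.cin, self.k, self.k)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.cin, co * self.k * self.k
        )
        cols2, (n2, hi, wi) = _im2col(g, self.k, self.k - 1 - self.pad)
        dx = cols2 @ Wflip.T
        dx = dx.reshape(n2, hi, wi, self.cin).transpose(0, 3, 1, 2)
        assert dx.shape == self._in_shape
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, memorising argmax indices for unpooling."""

    def forward(self, x):
        n, c, h, w = x.shape
        v = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self.indices = v.argmax(axis=-1)
        out = np.take_along_axis(v, self.indices[..., None], axis=-1)[..., 0]
        return out

    def backward(self, g):
        n, c, h2, w2 = g.shape
        z = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(z, self.indices[..., None], g[..., None], axis=-1)
        return (
            z.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )


class MaxUnpool2x2(Layer):
    """Places values at the positions a paired :class:`MaxPool2x2` kept."""

    def forward(self, x, indices):
        n, c, h2, w2 = x.shape
        self._indices = indices
        z = np.zeros((n, c, h2, w2, 4), dtype=x.dtype)
        np.put_along_axis(z, indices[..., None], x[..., None], axis=-1)
        return (
            z.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )

    def backward(self, g):
        n, c, h, w = g.shape
        v = (
            g.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        return np.take_along_axis(v, self._indices[..., None], axis=-1)[..., 0]


class UpsampleNearest2x(Layer):
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvStack(Layer):
    """``n_convs`` 3x3 conv+ReLU pairs; channel change happens in the first conv."""

    def __init__(self, cin, cout, n_convs, rng, dtype=np.float32):
        self.layers: list[Layer] = []
        c = cin
        for _ in range(n_convs):
            self.layers.append(Conv2d(c, cout, rng=rng, dtype=dtype))
            self.layers.append(ReLU())
            c = cout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ResBlock(Layer):
    """Two 3x3 convs with an identity (or 1x1-projected) shortcut, ReLU after the add."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, rng=rng, dtype=dtype)
        self.proj = Conv2d(cin, cout, k=1, pad=0, rng=rng, dtype=dtype) if cin != cout else None
        self.relu2 = ReLU()

    def params(self):
        layers = [self.conv1, self.conv2] + ([self.proj] if self.proj else [])
        return [p for layer in layers for p in layer.params()]

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        shortcut = self.proj.forward(x) if self.proj else x
        return self.relu2.forward(self.conv2.forward(h) + shortcut)

    def backward(self, g):
        g = self.relu2.backward(g)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_short = self.proj.backward(g) if self.proj else g
        return g_main + g_short
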