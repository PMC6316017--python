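"""Minimal convolutional encoder-decoder machinery in numpy.

The opposite-view synthesis models are small enough at test scale (64 x 64
depth maps, a few thousand parameters per layer) that a self-contained
im2col implementation with reverse-mode gradients and an Adam step keeps the
whole training loop deterministic, single-threaded and dependency-free.
Layers follow the usual (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "Softplus",
    "Linear",
    "Upsample2x",
    "Flatten",
    "Sequential",
    "InceptionBlock",
    "Adam",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (n, ho*wo, c*k*k)
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, k, k)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += \
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return xp[:, :, pad:hp - pad, pad:wp - pad] if pad else xp


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k=3, stride=1, pad=None, rng=None):
        super().__init__()
        pad = k // 2 if pad is None else pad
        self.k, self.stride, self.pad = k, stride, pad
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * k * k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._shape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        n = x.shape[0]
        y = cols @ self.w.T + self.b  # (n, L, c_out)
        return y.transpose(0, 2, 1).reshape(n, -1, ho, wo)

    def backward(self, dy):
        n, c_out, ho, wo = dy.shape
        dyf = dy.reshape(n, c_out, ho * wo).transpose(0, 2, 1)  # (n, L, c_out)
        self.grads[0][...] = np.einsum("nlo,nlk->ok", dyf, self._cols)
        self.grads[1][...] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.w  # (n, L, c_in*k*k)
        return _col2im(dcols, self._shape, self.k, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Softplus(Layer):
    """Smooth non-negative output activation (depth must be >= 0)."""

    def forward(self, x):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy):
        return dy / (1.0 + np.exp(np.clip(-self._x, -60.0, 60.0)))


class Linear(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w


class Upsample2x(Layer):
    """Nearest-neighbour upsampling (decoder upscaling step)."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params += lay.params
            self.grads += lay.grads

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class InceptionBlock(Layer):
    """Parallel convolutions with different kernel sizes, concatenated."""

    def __init__(self, c_in, c_branch, kernels=(3, 5, 7), stride=1, rng=None):
        super().__init__()
        self.branches = [Conv2d(c_in, c_branch, k=k, stride=stride, rng=rng)
                         for k in kernels]
        self.act = ReLU()
        for br in self.branches:
            self.params += br.params
            self.grads += br.grads

    @property
    def c_out(self):
        return sum(br.w.shape[0] for br in self.branches)

    def forward(self, x):
        self._splits = []
        outs = []
        for br in self.branches:
            outs.append(br.forward(x))
            self._splits.append(outs[-1].shape[1])
        return self.act.forward(np.concatenate(outs, axis=1))

    def backward(self, dy):
        dy = self.act.backward(dy)
        dx = None
        start = 0
        for br, width in zip(self.branches, self._splits):
            piece = br.backward(dy[:, start:start + width])
            dx = piece if dx is None else dx + piece
            start += width
        return dx


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
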