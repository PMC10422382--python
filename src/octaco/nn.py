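"""Minimal forward-pass convolutional network toolkit.

Implements just the layer types the retinal-OCT backbones need: strided
convolution (via ``sliding_window_view`` + matmul), ReLU, max/average
pooling, global average pooling, residual and densely-connected blocks,
and branch concatenation. Weights are He-initialized from a seeded
generator; the toolkit is inference-only — the trainable part of a
modified backbone is its softmax head, which lives in
:mod:`octaco.features`.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Sequential",
    "Residual",
    "Concat",
    "weights_checksum",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _pool_windows(x: np.ndarray, kernel, stride, pad, pad_value: float):
    """Return (N, C, Ho, Wo, kh, kw) sliding windows of a padded NCHW array."""
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(pad)
    if ph or pw:
        x = np.pad(
            x,
            ((0, 0), (0, 0), (ph, ph), (pw, pw)),
            mode="constant",
            constant_values=pad_value,
        )
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw, :, :]


class Layer:
    """Base class; subclasses implement ``forward`` and expose ``weights``."""

    weights: list

    def __init__(self):
        self.weights = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Layer):
    """2-D convolution, NCHW layout, symmetric zero padding."""

    def __init__(self, cin: int, cout: int, kernel, rng: np.random.Generator,
                 stride=1, pad=0):
        super().__init__()
        kh, kw = _pair(kernel)
        self.stride = _pair(stride)
        self.pad = _pair(pad)
        fan_in = cin * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(cout, cin, kh, kw)).astype(np.float32)
        self.weights = [self.w]

    def forward(self, x):
        win = _pool_windows(x, self.w.shape[2:], self.stride, self.pad, 0.0)
        n, c, ho, wo, kh, kw = win.shape
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wmat = self.w.reshape(self.w.shape[0], -1)
        out = col @ wmat.T
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x):
        return np.maximum(x, 0.0)


class MaxPool2d(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        super().__init__()
        self.kernel = _pair(kernel)
        self.stride = _pair(stride if stride is not None else kernel)
        self.pad = _pair(pad)

    def forward(self, x):
        win = _pool_windows(x, self.kernel, self.stride, self.pad, -np.inf)
        return win.max(axis=(4, 5))


class AvgPool2d(Layer):
    def __init__(self, kernel, stride=None, pad=0):
        super().__init__()
        self.kernel = _pair(kernel)
        self.stride = _pair(stride if stride is not None else kernel)
        self.pad = _pair(pad)

    def forward(self, x):
        win = _pool_windows(x, self.kernel, self.stride, self.pad, 0.0)
        return win.mean(axis=(4, 5))


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def forward(self, x):
        return x.mean(axis=(2, 3))


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def weights(self):
        return [w for lyr in self.layers for w in lyr.weights]

    @weights.setter
    def weights(self, value):  # Layer.__init__ assigns []; ignore
        pass

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x


class Residual(Layer):
    """y = relu(branch(x) + shortcut(x)); identity shortcut by default."""

    def __init__(self, branch: Layer, shortcut: Layer | None = None):
        super().__init__()
        self.branch = branch
        self.shortcut = shortcut

    @property
    def weights(self):
        w = list(self.branch.weights)
        if self.shortcut is not None:
            w += self.shortcut.weights
        return w

    @weights.setter
    def weights(self, value):
        pass

    def forward(self, x):
        s = x if self.shortcut is None else self.shortcut.forward(x)
        return np.maximum(self.branch.forward(x) + s, 0.0)


class Concat(Layer):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, *branches):
        super().__init__()
        self.branches = list(branches)

    @property
    def weights(self):
        return [w for b in self.branches for w in b.weights]

    @weights.setter
    def weights(self, value):
        pass

    def forward(self, x):
        return np.concatenate([b.forward(x) for b in self.branches], axis=1)


def weights_checksum(layer: Layer) -> str:
    """SHA-256 over all weight arrays, in traversal order."""
    h = hashlib.sha256()
    for w in layer.weights:
        h.update(np.ascontiguousarray(w).tobytes())
    return h.hexdigest()
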