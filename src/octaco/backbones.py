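"""Channel-faithful builds of the three modified CNN backbones.

Each builder returns a feature network mapping an NCHW image batch to the
global-average-pooled channel vector whose width matches the published
architecture: 2048 for ResNet-50, 1920 for DenseNet-201, 2048 for
InceptionV3. Convolutional weights are He-initialized from a seeded
generator (no pretrained ImageNet weights ship with this package); the
layer/stage structure, strides and channel progressions follow the
canonical architectures so that all width and shape contracts hold.

A fourth, much smaller ``tiny`` network with the same interface is
provided for desk-scale smoke tests of the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

from .nn import (
    AvgPool2d,
    Concat,
    Conv2d,
    GlobalAvgPool,
    Layer,
    MaxPool2d,
    ReLU,
    Residual,
    Sequential,
)

SUPPORTED_BACKBONES = ("resnet50", "densenet201", "inceptionv3", "tiny")

#: global-average-pool width of each supported architecture
FEATURE_WIDTHS = {
    "resnet50": 2048,
    "densenet201": 1920,
    "inceptionv3": 2048,
    "tiny": 64,
}


def _bottleneck(cin, mid, rng, stride=1):
    branch = Sequential(
        Conv2d(cin, mid, 1, rng), ReLU(),
        Conv2d(mid, mid, 3, rng, stride=stride, pad=1), ReLU(),
        Conv2d(mid, mid * 4, 1, rng),
    )
    shortcut = None
    if stride != 1 or cin != mid * 4:
        shortcut = Conv2d(cin, mid * 4, 1, rng, stride=stride)
    return Residual(branch, shortcut)


def _resnet50(rng) -> Sequential:
    layers = [
        Conv2d(3, 64, 7, rng, stride=2, pad=3), ReLU(),
        MaxPool2d(3, stride=2, pad=1),
    ]
    cin = 64
    for mid, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for i in range(blocks):
            layers.append(_bottleneck(cin, mid, rng, stride=stride if i == 0 else 1))
            cin = mid * 4
    layers.append(GlobalAvgPool())
    return Sequential(*layers)


class _DenseBlock(Layer):
    """Stack of bottleneck layers, each concatenating `growth` new channels."""

    def __init__(self, cin, n_layers, growth, rng):
        super().__init__()
        self.convs = []
        c = cin
        for _ in range(n_layers):
            self.convs.append(
                Sequential(
                    ReLU(), Conv2d(c, 4 * growth, 1, rng),
                    ReLU(), Conv2d(4 * growth, growth, 3, rng, pad=1),
                )
            )
            c += growth
        self.out_channels = c

    @property
    def weights(self):
        return [w for s in self.convs for w in s.weights]

    @weights.setter
    def weights(self, value):
        pass

    def forward(self, x):
        for conv in self.convs:
            x = np.concatenate([x, conv.forward(x)], axis=1)
        return x


def _densenet201(rng) -> Sequential:
    growth = 32
    layers = [
        Conv2d(3, 64, 7, rng, stride=2, pad=3), ReLU(),
        MaxPool2d(3, stride=2, pad=1),
    ]
    c = 64
    for i, n in enumerate((6, 12, 48, 32)):
        block = _DenseBlock(c, n, growth, rng)
        layers.append(block)
        c = block.out_channels
        if i < 3:  # transition: halve channels, halve resolution
            layers += [ReLU(), Conv2d(c, c // 2, 1, rng), AvgPool2d(2, stride=2)]
            c //= 2
    layers += [ReLU(), GlobalAvgPool()]
    return Sequential(*layers)


def _conv_relu(cin, cout, kernel, rng, stride=1, pad=0):
    return Sequential(Conv2d(cin, cout, kernel, rng, stride=stride, pad=pad), ReLU())


def _inception_a(cin, pool_proj, rng):
    return Concat(
        _conv_relu(cin, 64, 1, rng),
        Sequential(_conv_relu(cin, 48, 1, rng), _conv_relu(48, 64, 5, rng, pad=2)),
        Sequential(
            _conv_relu(cin, 64, 1, rng),
            _conv_relu(64, 96, 3, rng, pad=1),
            _conv_relu(96, 96, 3, rng, pad=1),
        ),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_relu(cin, pool_proj, 1, rng)),
    )


def _inception_b(cin, c7, rng):
    def h(ci, co):  # 1x7
        return _conv_relu(ci, co, (1, 7), rng, pad=(0, 3))

    def v(ci, co):  # 7x1
        return _conv_relu(ci, co, (7, 1), rng, pad=(3, 0))

    return Concat(
        _conv_relu(cin, 192, 1, rng),
        Sequential(_conv_relu(cin, c7, 1, rng), h(c7, c7), v(c7, 192)),
        Sequential(_conv_relu(cin, c7, 1, rng), v(c7, c7), h(c7, c7), v(c7, c7), h(c7, 192)),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_relu(cin, 192, 1, rng)),
    )


def _inception_c(cin, rng):
    def split(ci, co):
        return Concat(
            _conv_relu(ci, co, (1, 3), rng, pad=(0, 1)),
            _conv_relu(ci, co, (3, 1), rng, pad=(1, 0)),
        )

    return Concat(
        _conv_relu(cin, 320, 1, rng),
        Sequential(_conv_relu(cin, 384, 1, rng), split(384, 384)),
        Sequential(
            _conv_relu(cin, 448, 1, rng),
            _conv_relu(448, 384, 3, rng, pad=1),
            split(384, 384),
        ),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_relu(cin, 192, 1, rng)),
    )


def _inceptionv3(rng) -> Sequential:
    stem = [
        _conv_relu(3, 32, 3, rng, stride=2),
        _conv_relu(32, 32, 3, rng),
        _conv_relu(32, 64, 3, rng, pad=1),
        MaxPool2d(3, stride=2),
        _conv_relu(64, 80, 1, rng),
        _conv_relu(80, 192, 3, rng),
        MaxPool2d(3, stride=2),
    ]
    mixed = [
        _inception_a(192, 32, rng),   # -> 256
        _inception_a(256, 64, rng),   # -> 288
        _inception_a(288, 64, rng),   # -> 288
        Concat(                        # grid reduction -> 768
            _conv_relu(288, 384, 3, rng, stride=2),
            Sequential(
                _conv_relu(288, 64, 1, rng),
                _conv_relu(64, 96, 3, rng, pad=1),
                _conv_relu(96, 96, 3, rng, stride=2),
            ),
            MaxPool2d(3, stride=2),
        ),
        _inception_b(768, 128, rng),
        _inception_b(768, 160, rng),
        _inception_b(768, 160, rng),
        _inception_b(768, 192, rng),
        Concat(                        # grid reduction -> 1280
            Sequential(_conv_relu(768, 192, 1, rng), _conv_relu(192, 320, 3, rng, stride=2)),
            Sequential(
                _conv_relu(768, 192, 1, rng),
                _conv_relu(192, 192, (1, 7), rng, pad=(0, 3)),
                _conv_relu(192, 192, (7, 1), rng, pad=(3, 0)),
                _conv_relu(192, 192, 3, rng, stride=2),
            ),
            MaxPool2d(3, stride=2),
        ),
        _inception_c(1280, rng),      # -> 2048
        _inception_c(2048, rng),      # -> 2048
    ]
    return Sequential(*stem, *mixed, GlobalAvgPool())


def _tiny(rng) -> Sequential:
    return Sequential(
        Conv2d(3, 16, 3, rng, stride=2, pad=1), ReLU(),
        Conv2d(16, 32, 3, rng, stride=2, pad=1), ReLU(),
        MaxPool2d(2, stride=2),
        Conv2d(32, 64, 3, rng, stride=2, pad=1), ReLU(),
        GlobalAvgPool(),
    )


_BUILDERS = {
    "resnet50": _resnet50,
    "densenet201": _densenet201,
    "inceptionv3": _inceptionv3,
    "tiny": _tiny,
}


def build_feature_net(name: str, weight_seed: int = 0) -> Sequential:
    """Instantiate a backbone's feature network with seeded random weights."""
    if name not in _BUILDERS:
        raise ValueError(
            f"unsupported backbone {name!r}; supported: {', '.join(SUPPORTED_BACKBONES)}"
        )
    # per-architecture stream so identical seeds give identical weights
    seed = np.random.SeedSequence([weight_seed, zlib.crc32(name.encode())])
    return _BUILDERS[name](np.random.default_rng(seed))
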