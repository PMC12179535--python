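"""Convolutional backbones and dense layers for the MIL network.

Two encoders are provided, both ending in global average pooling followed
(where needed) by a linear projection to the 512-feature tile embedding:

* ``SmallCNN`` — a light 3-block strided encoder used for tests and
  desk-scale experiments (trains in minutes on one CPU).
* ``VGG19Backbone`` — the VGG-19 convolutional stack (randomly initialised;
  no pretrained weights are bundled) for full-scale use.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

FEATURE_DIM = 512


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.w)
        if self.b is not None:
            out = ag.add(out, self.b)
        return out

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])


class Conv2d:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = Tensor(rng.normal(0.0, scale, (k, k, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class SmallCNN:
    """Compact encoder: 2× average-pool stem, three strided 3×3 conv blocks.

    A 256×256 tile maps to a 16×16×32 feature map; GAP gives 32 channels
    which the shared projection lifts to the 512-feature contract.
    """

    out_channels = 32
    min_input = 16  # stem (2) × three stride-2 convs (8)

    def __init__(self, rng: np.random.Generator):
        self.stem_pool = 2
        self.convs = [
            Conv2d(3, 8, rng, stride=2),
            Conv2d(8, 16, rng, stride=2),
            Conv2d(16, 32, rng, stride=2),
        ]

    def feature_map(self, x: Tensor) -> Tensor:
        """Last conv activation map, (N, h, w, 32); input NHWC in [0, 1]."""
        h, w = x.data.shape[1:3]
        if h % self.min_input or w % self.min_input:
            raise ValueError(
                f"tile size ({h}×{w}) must be divisible by {self.min_input} "
                f"for the small_cnn backbone"
            )
        out = ag.avg_pool2d(x, self.stem_pool)
        for conv in self.convs:
            out = ag.relu(conv(out))
        return out

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()]


_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


class VGG19Backbone:
    """VGG-19 convolutional stack (randomly initialised), NHWC, GAP→512."""

    out_channels = 512
    min_input = 32  # five 2× max-pools

    def __init__(self, rng: np.random.Generator):
        self.layers = []
        c_in = 3
        for item in _VGG19_CFG:
            if item == "M":
                self.layers.append("M")
            else:
                self.layers.append(Conv2d(c_in, item, rng, stride=1))
                c_in = item

    def feature_map(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[1:3]
        if h % self.min_input or w % self.min_input:
            raise ValueError(
                f"tile size ({h}×{w}) must be divisible by {self.min_input} "
                f"for the vgg19_like backbone"
            )
        out = x
        for layer in self.layers:
            if layer == "M":
                out = ag.max_pool2d(out, 2)
            else:
                out = ag.relu(layer(out))
        return out

    def parameters(self):
        return [p for l in self.layers if l != "M" for p in l.parameters()]


BACKBONES = {"small_cnn": SmallCNN, "vgg19_like": VGG19Backbone}


def make_backbone(name: str, rng: np.random.Generator):
    try:
        return BACKBONES[name](rng)
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}"
        ) from None


class SGD:
    """Plain stochastic gradient descent (no momentum)."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None
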