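"""Network building blocks for the staining translator.

The generator is a U-Net: an encoder that halves resolution per level with
2x average pooling, a bottleneck, and a decoder that restores resolution
with nearest-neighbour upsampling, concatenating the matching encoder
feature map (skip connection) at each level.  The discriminator is a
patch-based conditional discriminator: it sees the input image stacked with
either the real target or the generated candidate and emits a grid of
real/fake logits, each judging one receptive patch.

All convolutions are stride-1 'same' 3x3 (1x1 for the logits head); He
initialisation scaled for leaky-ReLU encoders.  Tracked layers — the ones
whose activations the explainability tooling captures — are the generator's
convolutions, numbered from 1 in forward order.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    avg_pool2,
    bce_with_logits,
    concat_channels,
    conv2d,
    upsample2,
)


class Conv:
    """A stride-1 'same' convolution with owned weight/bias parameters."""

    def __init__(self, name: str, in_ch: int, out_ch: int, k: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.name = name
        self.k = k
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, k, k)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.k)

    @property
    def params(self):
        return [(self.name + ".weight", self.weight),
                (self.name + ".bias", self.bias)]


class Generator:
    """U-Net image-to-image generator over [-1, 1] RGB tensors.

    ``depth`` encoder/decoder levels, ``convs_per_level`` convolutions per
    level; tracked convolutional layers number
    ``2 * depth * convs_per_level + 3`` (stem + bottleneck + output head).
    The canonical configuration (depth 4, two convolutions per level) tracks
    19 layers.
    """

    def __init__(self, depth: int, base_channels: int, convs_per_level: int,
                 rng: np.random.Generator):
        self.depth = depth
        self.base_channels = base_channels
        self.convs_per_level = convs_per_level
        self.enc: list[list[Conv]] = []
        self.dec: list[list[Conv]] = []

        b = base_channels
        self.stem = Conv("g.stem", 3, b, 3, rng)
        ch = b
        for lvl in range(depth):
            out = b * 2 ** (lvl + 1)
            block = []
            for j in range(convs_per_level):
                block.append(Conv(f"g.enc{lvl}.{j}", ch, out, 3, rng))
                ch = out
            self.enc.append(block)
        self.bottleneck = Conv("g.bottleneck", ch, ch, 3, rng)
        for lvl in reversed(range(depth)):
            out = b * 2 ** lvl if lvl > 0 else b
            skip_ch = b * 2 ** lvl  # channels of the pre-pool encoder map
            block = []
            in_ch = ch + skip_ch
            for j in range(convs_per_level):
                block.append(Conv(f"g.dec{lvl}.{j}", in_ch, out, 3, rng))
                in_ch = out
            ch = out
            self.dec.append(block)
        self.head = Conv("g.head", ch, 3, 3, rng)

    @property
    def tracked_layer_count(self) -> int:
        return 2 * self.depth * self.convs_per_level + 3

    def forward(self, x: Tensor, record: list[Tensor] | None = None) -> Tensor:
        """Run the generator; optionally record each tracked layer's
        post-activation output (the output head records its tanh map)."""

        def track(t: Tensor) -> Tensor:
            if record is not None:
                record.append(t)
            return t

        h = track(self.stem(x).leaky_relu(0.2))
        skips = []
        for block in self.enc:
            skips.append(h)
            for conv in block:
                h = track(conv(h).leaky_relu(0.2))
            h = avg_pool2(h)
        h = track(self.bottleneck(h).leaky_relu(0.2))
        for block, skip in zip(self.dec, reversed(skips)):
            h = concat_channels(upsample2(h), skip)
            for conv in block:
                h = track(conv(h).relu())
        return track(self.head(h).tanh())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    @property
    def params(self):
        out = list(self.stem.params)
        for block in self.enc:
            for c in block:
                out += c.params
        out += self.bottleneck.params
        for block in self.dec:
            for c in block:
                out += c.params
        out += self.head.params
        return out


class Discriminator:
    """Conditional patch discriminator: (input, candidate) -> logits grid."""

    def __init__(self, base_channels: int, rng: np.random.Generator,
                 levels: int = 2):
        b = base_channels
        self.convs: list[Conv] = []
        ch = 6
        for lvl in range(levels):
            out = b * 2 ** lvl
            self.convs.append(Conv(f"d.conv{lvl}", ch, out, 3, rng))
            ch = out
        self.head = Conv("d.head", ch, 1, 1, rng)
        self.levels = levels

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        h = concat_channels(x, y)
        for conv in self.convs:
            h = avg_pool2(conv(h).leaky_relu(0.2))
        return self.head(h)

    __call__ = forward

    @property
    def params(self):
        out = []
        for c in self.convs:
            out += c.params
        out += self.head.params
        return out


class Adam:
    """Adam optimiser over named parameter lists."""

    def __init__(self, params, lr: float = 2e-3, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in params}
        self.v = {n: np.zeros_like(p.data) for n, p in params}

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, p in self.params:
            if p.grad is None:
                continue
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * p.grad
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * (
                p.grad * p.grad
            )
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


__all__ = [
    "Adam",
    "Conv",
    "Discriminator",
    "Generator",
    "Tensor",
    "avg_pool2",
    "bce_with_logits",
    "concat_channels",
    "upsample2",
]
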