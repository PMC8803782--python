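"""2D U-Net for slice-wise candidate segmentation.

A standard encoder-decoder with skip connections: ``depth`` pooling levels,
two 3x3 conv + ReLU per level, nearest-neighbour upsampling, channel
concatenation of the matching encoder feature map, and a final 1x1 conv
producing one logit per pixel (sigmoid applied by the loss / caller).
Channel widths double per level from ``base_channels``; both width and depth
are configurable so desk-scale training runs stay cheap without changing
the pipeline semantics.
"""

from __future__ import annotations

import numpy as np

from .core import ConvND, MaxPool, Param, ReLU, Upsample, collect_params


class _ConvBlock:
    """Two 3x3 conv + ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng, name: str):
        self.c1 = ConvND(in_ch, out_ch, 3, nd=2, rng=rng, name=f"{name}.c1")
        self.r1 = ReLU()
        self.c2 = ConvND(out_ch, out_ch, 3, nd=2, rng=rng, name=f"{name}.c2")
        self.r2 = ReLU()

    def layers(self):
        return [self.c1, self.r1, self.c2, self.r2]

    def forward(self, x, train=True):
        for l in self.layers():
            x = l.forward(x, train)
        return x

    def backward(self, d):
        for l in reversed(self.layers()):
            d = l.backward(d)
        return d


class UNet2D:
    """Slice-wise segmentation network: (N, in_channels, H, W) -> (N, 1, H, W) logits."""

    def __init__(
        self,
        in_channels: int = 2,
        base_channels: int = 32,
        depth: int = 4,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        widths = [base_channels * 2**l for l in range(depth + 1)]
        self.enc = []
        ch = in_channels
        for l in range(depth):
            self.enc.append(_ConvBlock(ch, widths[l], rng, f"enc{l}"))
            ch = widths[l]
        self.pools = [MaxPool(nd=2) for _ in range(depth)]
        self.bottleneck = _ConvBlock(ch, widths[depth], rng, "bottleneck")
        self.ups = [Upsample(nd=2) for _ in range(depth)]
        self.up_convs = []
        self.dec = []
        for l in reversed(range(depth)):
            self.up_convs.append(
                ConvND(widths[l + 1], widths[l], 3, nd=2, rng=rng, name=f"up{l}")
            )
            self.dec.append(_ConvBlock(2 * widths[l], widths[l], rng, f"dec{l}"))
        self.head = ConvND(widths[0], 1, 1, nd=2, rng=rng, name="head")

    def all_layers(self):
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for b in blocks for l in b.layers()] + self.up_convs + [self.head]

    def params(self) -> list[Param]:
        return collect_params(self.all_layers())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for l in range(self.depth):
            x = self.enc[l].forward(x, train)
            skips.append(x)
            x = self.pools[l].forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, l in enumerate(reversed(range(self.depth))):
            x = self.ups[i].forward(x, train)
            x = self.up_convs[i].forward(x, train)
            x = np.concatenate([skips[l], x], axis=1)
            x = self.dec[i].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        dskips = [None] * self.depth
        for i, l in zip(reversed(range(self.depth)), range(self.depth)):
            # decoder blocks were applied for levels depth-1 .. 0
            d = self.dec[i].backward(d)
            ch = self._skip_channels[l]
            dskips[l], d = d[:, :ch], d[:, ch:]
            d = self.up_convs[i].backward(d)
            d = self.ups[i].backward(d)
        d = self.bottleneck.backward(d)
        for l in reversed(range(self.depth)):
            d = self.pools[l].backward(d)
            d = d + dskips[l]
            d = self.enc[l].backward(d)
        return d
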