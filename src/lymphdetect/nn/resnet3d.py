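"""3D residual network for cube classification.

The default configuration follows the familiar 50-layer residual design
(7-voxel stem convolution, max pooling, bottleneck stages of 3/4/6/3 blocks,
global average pooling and a 2-way softmax head) applied to two-channel
64 mm cubes.  Depth, widths, stem kernel and block type are all
configurable so CPU-scale experiments can shrink the network without
changing pipeline semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BatchNorm,
    ConvND,
    Dense,
    GlobalAvgPool,
    MaxPool,
    Param,
    ReLU,
    collect_params,
)


@dataclass(frozen=True)
class ResNetSpec:
    """Architecture knobs. The default is the 50-layer bottleneck network."""

    block: str = "bottleneck"  # "bottleneck" | "basic"
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)
    base_width: int = 64
    stem_width: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    batchnorm: bool = True

    @classmethod
    def tiny(cls) -> "ResNetSpec":
        """A shrunken configuration for CPU-scale runs."""
        return cls(
            block="basic",
            stage_blocks=(1, 1),
            base_width=8,
            stem_width=8,
            stem_kernel=5,
            stem_stride=4,
            batchnorm=True,
        )


class _Identity:
    def forward(self, x, train=True):
        return x

    def backward(self, d):
        return d

    def params(self):
        return []


class _Block:
    """Residual block (basic: two 3^3 convs; bottleneck: 1-3-1 with 4x expansion)."""

    def __init__(self, in_ch: int, width: int, stride: int, spec: ResNetSpec, rng, name: str):
        bn = spec.batchnorm
        mk_bn = lambda c, n: BatchNorm(c, name=n) if bn else _Identity()
        if spec.block == "bottleneck":
            out_ch = 4 * width
            self.main = [
                ConvND(in_ch, width, 1, 1, nd=3, rng=rng, name=f"{name}.c1"),
                mk_bn(width, f"{name}.b1"),
                ReLU(),
                ConvND(width, width, 3, stride, nd=3, rng=rng, name=f"{name}.c2"),
                mk_bn(width, f"{name}.b2"),
                ReLU(),
                ConvND(width, out_ch, 1, 1, nd=3, rng=rng, name=f"{name}.c3"),
                mk_bn(out_ch, f"{name}.b3"),
            ]
        elif spec.block == "basic":
            out_ch = width
            self.main = [
                ConvND(in_ch, width, 3, stride, nd=3, rng=rng, name=f"{name}.c1"),
                mk_bn(width, f"{name}.b1"),
                ReLU(),
                ConvND(width, width, 3, 1, nd=3, rng=rng, name=f"{name}.c2"),
                mk_bn(width, f"{name}.b2"),
            ]
        else:
            raise ValueError(f"unknown block type {spec.block!r}")
        self.out_ch = out_ch
        if stride != 1 or in_ch != out_ch:
            self.proj = [
                ConvND(in_ch, out_ch, 1, stride, nd=3, rng=rng, name=f"{name}.proj"),
                mk_bn(out_ch, f"{name}.projbn"),
            ]
        else:
            self.proj = []
        self.relu_out = ReLU()

    def layers(self):
        return self.main + self.proj + [self.relu_out]

    def forward(self, x, train=True):
        h = x
        for l in self.main:
            h = l.forward(h, train)
        s = x
        for l in self.proj:
            s = l.forward(s, train)
        return self.relu_out.forward(h + s, train)

    def backward(self, d):
        d = self.relu_out.backward(d)
        ds = d
        for l in reversed(self.proj):
            ds = l.backward(ds)
        dh = d
        for l in reversed(self.main):
            dh = l.backward(dh)
        return dh + ds


class ResNet3D:
    """Cube classifier: (N, in_channels, D, H, W) -> (N, 2) logits."""

    def __init__(
        self,
        in_channels: int = 2,
        spec: ResNetSpec | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.spec = spec = spec or ResNetSpec()
        bn = spec.batchnorm
        self.stem = [
            ConvND(in_channels, spec.stem_width, spec.stem_kernel, spec.stem_stride, nd=3, rng=rng, name="stem"),
            BatchNorm(spec.stem_width, name="stembn") if bn else _Identity(),
            ReLU(),
            MaxPool(nd=3),
        ]
        self.blocks: list[_Block] = []
        ch = spec.stem_width
        for si, n_blocks in enumerate(spec.stage_blocks):
            width = spec.base_width * 2**si
            for bi in range(n_blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                blk = _Block(ch, width, stride, spec, rng, f"s{si}b{bi}")
                self.blocks.append(blk)
                ch = blk.out_ch
        self.gap = GlobalAvgPool()
        self.fc = Dense(ch, 2, rng=rng, name="fc")

    def all_layers(self):
        return list(self.stem) + [l for b in self.blocks for l in b.layers()] + [self.fc]

    def params(self) -> list[Param]:
        return collect_params(self.all_layers())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.stem:
            x = l.forward(x, train)
        for b in self.blocks:
            x = b.forward(x, train)
        x = self.gap.forward(x, train)
        return self.fc.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dlogits)
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        for l in reversed(self.stem):
            d = l.backward(d)
        return d
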