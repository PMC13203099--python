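"""Convolutional backbones exposing their last three stage outputs.

Two architectures are provided:

* ``tiny`` — a 4-block CNN (stride-1 stem + three 2x-downsampling blocks,
  total stride 8) sized for CPU experiments; on a 64x64 input the last three
  stages have spatial sides 32, 16 and 8.
* ``resnet`` — a residual network with ResNet50's stage geometry (stem at
  stride 4, four stages at total strides 4/8/16/32) but small configurable
  widths; on a 256x256 input the last three stages have sides 32, 16 and 8.

Both return multi-scale features deepest-first for the fusion module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Conv2d, Module


class ShapeError(ValueError):
    pass


@dataclass
class BackboneConfig:
    name: str = "tiny"
    pretrained: bool = False
    widths: tuple = ()  # per-block channel counts; () -> architecture default

    def __post_init__(self):
        if self.name not in ("tiny", "resnet"):
            raise ValueError(f"unknown backbone {self.name!r}; "
                             "expected 'tiny' or 'resnet'")
        if self.pretrained:
            raise ValueError("no pretrained weights are distributed with this "
                             "package; set backbone.pretrained to false")


@dataclass
class BackboneFeatures:
    """Last three stage outputs, deepest first."""

    maps: list  # three Tensors, each (B, C_k, H_k, W_k)

    def __post_init__(self):
        sides = [m.shape[-1] for m in self.maps]
        if sorted(sides) != sides:
            raise ShapeError("maps must be ordered deepest (smallest side) first")


class TinyBackbone(Module):
    """Stride-1 stem block followed by three 2x-downsampling conv blocks."""

    total_stride = 8
    default_widths = (8, 16, 32, 64)

    def __init__(self, widths=(), in_channels: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        widths = tuple(widths) or self.default_widths
        if len(widths) != 4:
            raise ValueError("tiny backbone takes exactly 4 block widths")
        chans = (in_channels,) + widths
        self.convs = [Conv2d(chans[k], chans[k + 1], rng=rng, dtype=dtype)
                      for k in range(4)]

    def __call__(self, x: Tensor) -> list[Tensor]:
        outs = []
        h = self.convs[0](x)
        h = ad.relu(h)
        outs.append(h)
        for conv in self.convs[1:]:
            h = ad.maxpool2d(h, 2)
            h = ad.relu(conv(h))
            outs.append(h)
        return outs


class _ResStage(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.conv1 = Conv2d(cin, cout, rng=rng, dtype=dtype)
        self.conv2 = Conv2d(cout, cout, rng=rng, dtype=dtype)
        self.proj = Conv2d(cin, cout, k=1, pad=0, bias=False, rng=rng,
                           dtype=dtype) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.conv1(x))
        h = self.conv2(h)
        skip = self.proj(x) if self.proj is not None else x
        return ad.relu(ad.add(h, skip))


class ResNetBackbone(Module):
    """Residual CNN with ResNet50 stage strides (4, 8, 16, 32)."""

    total_stride = 32
    default_widths = (8, 16, 32, 64)

    def __init__(self, widths=(), in_channels: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        widths = tuple(widths) or self.default_widths
        if len(widths) != 4:
            raise ValueError("resnet backbone takes exactly 4 stage widths")
        self.stem = Conv2d(in_channels, widths[0], k=3, stride=2, pad=1,
                           rng=rng, dtype=dtype)
        chans = (widths[0],) + widths
        self.stages = [_ResStage(chans[k], chans[k + 1], rng, dtype=dtype)
                       for k in range(4)]

    def __call__(self, x: Tensor) -> list[Tensor]:
        h = ad.relu(self.stem(x))
        h = ad.maxpool2d(h, 2)  # total stride 4 entering stage 1
        outs = []
        for k, stage in enumerate(self.stages):
            if k > 0:
                h = ad.maxpool2d(h, 2)
            h = stage(h)
            outs.append(h)
        return outs


def make_backbone(config: BackboneConfig,
                  rng: np.random.Generator | None = None,
                  dtype=np.float64) -> Module:
    cls = TinyBackbone if config.name == "tiny" else ResNetBackbone
    return cls(widths=config.widths, rng=rng, dtype=dtype)


def extract_multiscale(image_batch, backbone: Module) -> BackboneFeatures:
    """Run the backbone and return its three deepest stage outputs, deepest first.

    ``image_batch``: Tensor or array of shape (B, C, H, W) with H == W.
    """
    if not isinstance(image_batch, Tensor):
        image_batch = Tensor(image_batch)
    side = image_batch.shape[-1]
    if image_batch.shape[-2] != side:
        raise ShapeError("images must be square")
    if side % backbone.total_stride:
        raise ShapeError(f"image side {side} not divisible by the backbone's "
                         f"total stride {backbone.total_stride}")
    outs = backbone(image_batch)
    return BackboneFeatures(maps=outs[-1:-4:-1])
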