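"""Multi-scale feature fusion and the linear classification head.

The three deepest backbone maps are pooled to a common spatial size (max
pooling for the deepest map, average pooling for the shallower two), projected
to a common channel count by 1x1 convolutions, optionally passed through
single-head scaled dot-product self-attention plus cross-layer attention
(queries from the deepest map), and concatenated along channels into the fused
map X. Classification applies global average pooling followed by a linear
head; each column of the head's weight matrix doubles as the per-label
prototype used by the label-specific feature extractor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BackboneFeatures
from .errors import ValidationError
from .layers import Conv2d, Linear, Module


@dataclass
class FusionConfig:
    depth: int = 3              # how many of the three maps to fuse
    attention: bool = True
    common_channels: int | None = None  # None -> min of used map channels
    pool_stride: int = 2        # max-pool factor applied to the deepest map

    def __post_init__(self):
        if self.depth not in (1, 2, 3):
            raise ValidationError(f"fusion.depth must be 1, 2 or 3, got {self.depth}")
        if self.pool_stride < 1:
            raise ValidationError("fusion.pool_stride must be >= 1")


@dataclass
class FusedFeatureMap:
    """Fused representation X of a single image, shape (C, H, W)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("FusedFeatureMap expects a (C,H,W) array")
        if not np.isfinite(self.values).all():
            raise ValidationError("FusedFeatureMap entries must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ClassifierHead:
    """Linear head: weights (C x N), bias (N)."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise ValidationError("head weights must be CxN with length-N bias")

    @property
    def n_labels(self) -> int:
        return self.weights.shape[1]


class _Attention(Module):
    """Single-head scaled dot-product attention over spatial tokens."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.wq = Linear(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.wk = Linear(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.wv = Linear(channels, channels, bias=False, rng=rng, dtype=dtype)
        self.scale = 1.0 / np.sqrt(channels)

    def __call__(self, q_tokens: Tensor, kv_tokens: Tensor) -> Tensor:
        q = self.wq(q_tokens)                     # (B, S, C)
        k = self.wk(kv_tokens)
        v = self.wv(kv_tokens)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 2, 1))), self.scale)
        attn = ad.softmax(scores, axis=-1)        # (B, S, S)
        return ad.matmul(attn, v)


class FeatureFusion(Module):
    """Pool + project + attend + concatenate the deepest `depth` maps."""

    def __init__(self, map_channels: list[int], config: FusionConfig,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        if config.depth > len(map_channels):
            raise ValidationError(
                f"fusion.depth={config.depth} exceeds the {len(map_channels)} "
                "available maps")
        self.config = config
        used = list(map_channels[:config.depth])
        self.common = config.common_channels or min(used)
        self.projs = [Conv2d(c, self.common, k=1, pad=0, rng=rng, dtype=dtype)
                      for c in used]
        self.use_attention = config.attention and config.depth > 1
        if self.use_attention:
            self.self_attn = [_Attention(self.common, rng, dtype) for _ in used]
            self.cross_attn = [_Attention(self.common, rng, dtype)
                               for _ in used[1:]]

    @property
    def out_channels(self) -> int:
        return self.config.depth * self.common

    def __call__(self, feats: BackboneFeatures) -> Tensor:
        maps = feats.maps[: self.config.depth]
        deep_side = maps[0].shape[-1]
        if deep_side % self.config.pool_stride:
            raise ValidationError(
                f"deepest map side {deep_side} not divisible by "
                f"pool_stride {self.config.pool_stride}")
        target = deep_side // self.config.pool_stride
        pooled = [ad.maxpool2d(maps[0], self.config.pool_stride)]
        for m in maps[1:]:
            ratio = m.shape[-1] // target
            if ratio * target != m.shape[-1]:
                raise ValidationError("map side not divisible down to target size")
            pooled.append(ad.avgpool2d(m, ratio))
        projected = [proj(p) for proj, p in zip(self.projs, pooled)]
        if not self.use_attention:
            return ad.concat(projected, axis=1)

        b = projected[0].shape[0]
        s = target * target
        tokens = [ad.transpose(p.reshape((b, self.common, s)), (0, 2, 1))
                  for p in projected]
        out_tokens = [ad.add(tokens[0], self.self_attn[0](tokens[0], tokens[0]))]
        for k in range(1, len(tokens)):
            t = ad.add(tokens[k], self.self_attn[k](tokens[k], tokens[k]))
            t = ad.add(t, self.cross_attn[k - 1](tokens[0], tokens[k]))
            out_tokens.append(t)
        out_maps = [ad.transpose(t, (0, 2, 1)).reshape((b, self.common,
                                                        target, target))
                    for t in out_tokens]
        return ad.concat(out_maps, axis=1)


def fuse_features(feats: BackboneFeatures, fusion: FeatureFusion) -> Tensor:
    """Functional alias for applying a fusion module to backbone features."""
    return fusion(feats)


def classify(x, head: ClassifierHead):
    """Per-label logits from a fused map: head^T . spatial-mean(X) + bias.

    Accepts a FusedFeatureMap / (C,H,W) array (returns a length-N array) or a
    Tensor of shape (B,C,H,W) for the differentiable path.
    """
    if isinstance(x, Tensor):
        if x.shape[1] != head.weights.shape[0]:
            raise ValidationError(
                f"channel mismatch: X has {x.shape[1]}, head expects "
                f"{head.weights.shape[0]}")
        pooled = x.mean(axis=(2, 3))
        return ad.add(ad.matmul(pooled, Tensor(head.weights)),
                      Tensor(head.bias))
    values = x.values if isinstance(x, FusedFeatureMap) else np.asarray(x)
    if values.shape[0] != head.weights.shape[0]:
        raise ValidationError(
            f"channel mismatch: X has {values.shape[0]} channels, head "
            f"expects {head.weights.shape[0]}")
    pooled = values.mean(axis=(1, 2))
    return head.weights.T @ pooled + head.bias
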