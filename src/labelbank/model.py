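"""The end-to-end classification network: backbone -> fusion -> linear head.

Grayscale inputs are replicated to three channels at the entry point, matching
the convention of backbones designed for RGB input.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import BackboneConfig, extract_multiscale, make_backbone
from .errors import ValidationError
from .fusion import ClassifierHead, FeatureFusion, FusionConfig
from .layers import Linear, Module
from .lsfe import feature_dim


class LabelNet(Module):
    """Backbone + multi-scale fusion + linear multi-label head."""

    def __init__(self, n_labels: int, backbone_config: BackboneConfig,
                 fusion_config: FusionConfig,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.n_labels = n_labels
        self.dtype = dtype
        self.backbone_config = backbone_config
        self.fusion_config = fusion_config
        self.backbone = make_backbone(backbone_config, rng=rng, dtype=dtype)
        widths = (tuple(backbone_config.widths)
                  or self.backbone.default_widths)
        map_channels = list(widths[::-1][:3])  # deepest first
        self.fusion = FeatureFusion(map_channels, fusion_config, rng=rng,
                                    dtype=dtype)
        self.head = Linear(self.fusion.out_channels, n_labels, rng=rng,
                           dtype=dtype)

    # -- forward -----------------------------------------------------------

    def _to_rgb(self, images) -> Tensor:
        arr = np.asarray(images, dtype=self.dtype)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3:  # (B, H, W) grayscale -> replicate channels
            arr = np.repeat(arr[:, None], 3, axis=1)
        elif arr.ndim != 4:
            raise ValidationError("images must be (B,H,W) or (B,C,H,W)")
        return Tensor(arr)

    def forward(self, images) -> tuple[Tensor, Tensor]:
        """Return (fused map X (B,C,H,W), logits (B,N))."""
        x = self._to_rgb(images)
        feats = extract_multiscale(x, self.backbone)
        fused = self.fusion(feats)
        pooled = fused.mean(axis=(2, 3))
        logits = self.head(pooled)
        return fused, logits

    def __call__(self, images):
        return self.forward(images)

    # -- inference helpers ---------------------------------------------------

    def predict_proba(self, images, batch_size: int = 40) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        out = []
        for start in range(0, arr.shape[0], batch_size):
            _, logits = self.forward(arr[start:start + batch_size])
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out, axis=0)

    def classifier_head(self) -> ClassifierHead:
        bias = (self.head.bias.data if self.head.bias is not None
                else np.zeros(self.n_labels))
        return ClassifierHead(weights=self.head.weight.data.copy(),
                              bias=bias.copy())

    def label_feature_dim(self, image_side: int,
                          reduce_mode: str = "flatten") -> int:
        if image_side % self.backbone.total_stride:
            raise ValidationError(
                f"image side {image_side} not divisible by backbone stride "
                f"{self.backbone.total_stride}")
        deep = image_side // self.backbone.total_stride
        target = deep // self.fusion_config.pool_stride
        return feature_dim(self.fusion.out_channels, target, target, reduce_mode)
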