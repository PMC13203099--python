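"""Label-specific feature extraction.

The fused map X (C,H,W) is modulated channel-wise by each column of the
classifier weight matrix, yielding one map per label without summing over
channels: F[n,c,h,w] = X[c,h,w] * W[c,n]. Each per-label map is then reduced
to a vector, either by a literal row-major flatten (d = C*H*W, the default) or
by global average pooling per channel (d = C, a memory-saving alternative).

The classifier bias does not participate in the projection. Flatten order is
fixed as row-major (channel slowest, then row, then column) and is recorded in
pool file headers so stored banks remain portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import ValidationError
from .fusion import ClassifierHead, FusedFeatureMap

FLATTEN_ORDER = "c,h,w"
REDUCE_MODES = ("flatten", "gap")


@dataclass
class LabelSpecificMapStack:
    """Per-label modulated maps F, shape (N, C, H, W)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValidationError("LabelSpecificMapStack expects (N,C,H,W)")

    @property
    def n_labels(self) -> int:
        return self.values.shape[0]


@dataclass
class LabelSpecificFeature:
    """Compact per-label descriptor Z_i."""

    vector: np.ndarray
    label_index: int

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def project_label_specific(x, head: ClassifierHead) -> LabelSpecificMapStack:
    """F[n,c,h,w] = X[c,h,w] * W[c,n]; channels are kept, not summed."""
    values = x.values if isinstance(x, FusedFeatureMap) else np.asarray(x, float)
    if values.shape[0] != head.weights.shape[0]:
        raise ValidationError(
            f"channel mismatch: X has {values.shape[0]} channels, head has "
            f"{head.weights.shape[0]} weight rows")
    # (N, C, 1, 1) * (1, C, H, W)
    w = head.weights.T[:, :, None, None]
    return LabelSpecificMapStack(values=w * values[None])


def flatten_feature(stack: LabelSpecificMapStack, i: int,
                    reduce_mode: str = "flatten") -> LabelSpecificFeature:
    """Reduce the i-th per-label map to a vector (0-based label index)."""
    if reduce_mode not in REDUCE_MODES:
        raise ValidationError(f"reduce_mode must be one of {REDUCE_MODES}")
    if not 0 <= i < stack.n_labels:
        raise IndexError(f"label index {i} out of range [0, {stack.n_labels})")
    fi = stack.values[i]
    if reduce_mode == "flatten":
        vec = fi.reshape(-1)  # row-major: c slowest, then h, then w
    else:
        vec = fi.mean(axis=(1, 2))
    return LabelSpecificFeature(vector=vec, label_index=i)


def feature_dim(channels: int, height: int, width: int,
                reduce_mode: str = "flatten") -> int:
    if reduce_mode not in REDUCE_MODES:
        raise ValidationError(f"reduce_mode must be one of {REDUCE_MODES}")
    return channels * height * width if reduce_mode == "flatten" else channels


def project_batch(x: Tensor, weight: Tensor, reduce_mode: str = "flatten") -> Tensor:
    """Differentiable batched projection: (B,C,H,W) x (C,N) -> (B,N,d).

    Gradients flow into both the fused map and the classifier weights; vectors
    stored in feature pools are taken from .data and carry no gradient.
    """
    if reduce_mode not in REDUCE_MODES:
        raise ValidationError(f"reduce_mode must be one of {REDUCE_MODES}")
    b, c, h, w = x.shape
    if weight.shape[0] != c:
        raise ValidationError(
            f"channel mismatch: X has {c} channels, weights have {weight.shape[0]} rows")
    n = weight.shape[1]
    xr = x.reshape((b, 1, c, h * w))
    wr = weight.transpose(1, 0).reshape((1, n, c, 1))
    f = xr * wr                                  # (B, N, C, H*W)
    if reduce_mode == "flatten":
        return f.reshape((b, n, c * h * w))
    return f.mean(axis=3)
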