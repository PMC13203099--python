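"""Configuration schema, YAML loading and seed fan-out.

A single YAML file configures every stage. Unknown keys are rejected by name,
defaults follow the reference training recipe (256x256 inputs, batch 40,
learning rate 1e-3, Adam betas 0.9/0.999, weight decay 1e-4, pool capacity
200), and one global seed fans out into named substreams (data order, model
init, augmentation, K-Means) so each module is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .errors import ValidationError
from .fusion import FusionConfig


@dataclass
class DataSection:
    image_side: int = 256
    uncertain: str = "to_zero"  # mapping for -1 labels in real CSV tables

    def __post_init__(self):
        if self.image_side < 32:
            raise ValidationError("data.image_side must be >= 32")
        if self.uncertain not in ("to_zero", "to_one", "drop"):
            raise ValidationError(
                "data.uncertain must be to_zero, to_one or drop")


@dataclass
class LsfeSection:
    reduce: str = "flatten"

    def __post_init__(self):
        if self.reduce not in ("flatten", "gap"):
            raise ValidationError("lsfe.reduce must be 'flatten' or 'gap'")


@dataclass
class PoolSection:
    num: int = 200
    gamma: float = 0.1          # noise-augmentation scale, in bank-SD units
    update_every: str = "sample"

    def __post_init__(self):
        if self.num < 1:
            raise ValidationError("pool.num must be >= 1")
        if self.gamma < 0:
            raise ValidationError("pool.gamma must be >= 0")
        if self.update_every not in ("sample", "epoch"):
            raise ValidationError("pool.update_every must be 'sample' or 'epoch'")


@dataclass
class LossSection:
    aggregation: str = "sum"
    align_weight: float = 1.0
    margin_weight: float = 1.0
    threshold: float = 0.5      # decision threshold for "correctly classified"

    def __post_init__(self):
        if self.aggregation not in ("sum", "mean"):
            raise ValidationError("loss.aggregation must be 'sum' or 'mean'")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("loss.threshold must lie in (0, 1)")


@dataclass
class TrainSection:
    epochs: int = 5
    batch_size: int = 40
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4

    def __post_init__(self):
        if self.epochs < 0:
            raise ValidationError("train.epochs must be >= 0")
        if self.batch_size < 1:
            raise ValidationError("train.batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("train.learning_rate must be > 0")


_SECTIONS = {
    "data": DataSection,
    "backbone": BackboneConfig,
    "fusion": FusionConfig,
    "lsfe": LsfeSection,
    "pool": PoolSection,
    "loss": LossSection,
    "train": TrainSection,
}


@dataclass
class Config:
    seed: int = 0
    data: DataSection = field(default_factory=DataSection)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    lsfe: LsfeSection = field(default_factory=LsfeSection)
    pool: PoolSection = field(default_factory=PoolSection)
    loss: LossSection = field(default_factory=LossSection)
    train: TrainSection = field(default_factory=TrainSection)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["backbone"]["widths"] = list(d["backbone"]["widths"])
        return d


def config_from_dict(raw: dict | None) -> Config:
    raw = dict(raw or {})
    kwargs = {}
    if "seed" in raw:
        seed = raw.pop("seed")
        if not isinstance(seed, int):
            raise ValidationError(f"seed must be an integer, got {seed!r}")
        kwargs["seed"] = seed
    for name, cls in _SECTIONS.items():
        if name not in raw:
            continue
        section = raw.pop(name)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ValidationError(f"section {name!r} must be a mapping")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(section) - allowed
        if unknown:
            raise ValidationError(
                f"unknown key(s) in section {name!r}: {sorted(unknown)}")
        try:
            kwargs[name] = cls(**section)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"in section {name!r}: {exc}") from exc
    if raw:
        raise ValidationError(f"unknown top-level key(s): {sorted(raw)}")
    return Config(**kwargs)


def load_config(path) -> Config:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ValidationError("config file must contain a YAML mapping")
    return config_from_dict(raw)


def dump_config(config: Config) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=True)


def substream_seed(seed: int, name: str) -> int:
    """Deterministic named substream of the global seed, below 2^31."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2 ** 31)
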