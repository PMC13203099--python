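"""Two-stage training orchestration.

Stage 1 (label-aware pre-training) optimises the backbone, fusion and head
with the classification loss only, then initialises the per-label feature
banks in a single pass: for every sample and label, the label-specific vector
is admitted iff the thresholded prediction matches the true label, after
which every bank is brought to exactly Num rows.

Stage 2 (feature-constrained fine-tuning) adds the align and margin hinge
terms computed against the current pool to the objective, backpropagates
through the label-specific features (the stored bank vectors are gradient-free
constants), and after each optimiser step refreshes the pool with the batch's
correctly classified vectors via least-similar eviction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .config import Config, config_from_dict, substream_seed
from .errors import PoolError, ValidationError
from .layers import Adam
from .losses import batch_contrastive, bce_with_logits
from .lsfe import project_batch
from .model import LabelNet
from .pool import FeaturePool, PoolBuilder, build_pool
from .synthetic import LabeledImageSet

__version__ = "0.1.0"


@dataclass
class Checkpoint:
    model: LabelNet
    config: Config
    label_names: list[str]
    log: list[dict] = field(default_factory=list)


def build_model(config: Config, n_labels: int) -> LabelNet:
    rng = np.random.default_rng(substream_seed(config.seed, "init"))
    return LabelNet(n_labels, config.backbone, config.fusion, rng=rng)


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    arrays = {f"param::{k}": v for k, v in ckpt.model.state_dict().items()}
    meta = {"config": ckpt.config.to_dict(),
            "label_names": ckpt.label_names,
            "version": __version__}
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.array(json.dumps(meta)), **arrays)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> Checkpoint:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        state = {k.removeprefix("param::"): archive[k]
                 for k in archive.files if k.startswith("param::")}
    config = config_from_dict(meta["config"])
    model = build_model(config, len(meta["label_names"]))
    model.load_state_dict(state)
    return Checkpoint(model=model, config=config,
                      label_names=meta["label_names"])


# ---------------------------------------------------------------------------
# shared epoch loop
# ---------------------------------------------------------------------------

def _check_dataset(config: Config, dataset: LabeledImageSet, n_labels: int):
    if dataset.n_labels != n_labels:
        raise ValidationError(
            f"dataset has {dataset.n_labels} labels, model expects {n_labels}")
    side = dataset.images.shape[-1]
    if side != config.data.image_side:
        raise ValidationError(
            f"dataset images are {side}px, config.data.image_side is "
            f"{config.data.image_side}")


def _train_loop(model: LabelNet, dataset: LabeledImageSet, config: Config,
                pool: FeaturePool | None, epochs: int) -> list[dict]:
    """One optimisation loop; with pool=None this is classification-only
    training (Stage 1 and the no-pool ablation), otherwise Stage 2."""
    tr = config.train
    opt = Adam(model.parameters(), lr=tr.learning_rate, beta1=tr.beta1,
               beta2=tr.beta2, weight_decay=tr.weight_decay)
    rng = np.random.default_rng(substream_seed(config.seed, "data"))
    thr = config.loss.threshold
    agg_mean = config.loss.aggregation == "mean"
    log: list[dict] = []
    step = 0
    n = dataset.n_samples
    for epoch in range(epochs):
        perm = rng.permutation(n)
        epoch_events: list[tuple[np.ndarray, int, int]] = []
        for start in range(0, n, tr.batch_size):
            idx = perm[start:start + tr.batch_size]
            images = dataset.images[idx]
            y = dataset.labels[idx].astype(np.float64)
            fused, logits = model.forward(images)
            l_cls = bce_with_logits(logits, y)
            n_updates = 0
            if pool is not None:
                z = project_batch(fused, model.head.weight,
                                  config.lsfe.reduce)
                align, margin, _, _ = batch_contrastive(z, pool, y)
                align = align * config.loss.align_weight
                margin = margin * config.loss.margin_weight
                axis_agg = (lambda t: t.mean(axis=1)) if agg_mean \
                    else (lambda t: t.sum(axis=1))
                l_align = axis_agg(align).mean()
                l_margin = axis_agg(margin).mean()
                l_final = l_cls + l_align + l_margin
            else:
                z = None
                l_align = l_margin = Tensor(0.0)
                l_final = l_cls
            model.zero_grad()
            l_final.backward()
            opt.step()
            if pool is not None:
                probs = 1.0 / (1.0 + np.exp(-logits.data))
                correct = (probs >= thr) == (y == 1)
                events = [(z.data[b, i].copy(), int(i), int(y[b, i]))
                          for b, i in np.argwhere(correct)]
                if config.pool.update_every == "sample":
                    for zv, i, yi in events:
                        pool.update(zv, i, yi)
                    n_updates = len(events)
                else:
                    epoch_events.extend(events)
            step += 1
            log.append({
                "step": step, "epoch": epoch,
                "l_cls": l_cls.item(),
                "l_align": l_align.item(),
                "l_margin": l_margin.item(),
                "l_final": l_final.item(),
                "pool_updates": n_updates,
            })
        if pool is not None and config.pool.update_every == "epoch":
            for zv, i, yi in epoch_events:
                pool.update(zv, i, yi)
            if log:
                log[-1]["pool_updates"] = len(epoch_events)
    return log


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def pretrain(config: Config, train_set: LabeledImageSet,
             model: LabelNet | None = None) -> Checkpoint:
    """Stage 1: optimise with the classification loss only."""
    if model is None:
        model = build_model(config, train_set.n_labels)
    _check_dataset(config, train_set, model.n_labels)
    log = _train_loop(model, train_set, config, pool=None,
                      epochs=config.train.epochs)
    return Checkpoint(model=model, config=config,
                      label_names=list(train_set.label_names), log=log)


def _batched_label_features(model: LabelNet, images: np.ndarray,
                            reduce_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Inference-only pass: probabilities (B,N) and features Z (B,N,d)."""
    fused, logits = model.forward(images)
    x = fused.data                       # (B, C, H, W)
    w = model.head.weight.data           # (C, N)
    b, c, h, wd = x.shape
    f = w.T[None, :, :, None] * x.reshape(b, 1, c, h * wd)
    z = f.reshape(b, w.shape[1], c * h * wd) if reduce_mode == "flatten" \
        else f.mean(axis=3)
    probs = 1.0 / (1.0 + np.exp(-logits.data))
    return probs, z


def initialize_pool(ckpt: Checkpoint, train_set: LabeledImageSet,
                    num: int | None = None,
                    seed: int | None = None) -> FeaturePool:
    """Single admission pass over the data followed by bank sizing."""
    config = ckpt.config
    model = ckpt.model
    _check_dataset(config, train_set, model.n_labels)
    num = num if num is not None else config.pool.num
    seed = seed if seed is not None else substream_seed(config.seed, "pool")
    d = model.label_feature_dim(config.data.image_side, config.lsfe.reduce)
    builder = PoolBuilder(list(train_set.label_names), d)
    thr = config.loss.threshold
    bs = config.train.batch_size
    for start in range(0, train_set.n_samples, bs):
        images = train_set.images[start:start + bs]
        y = train_set.labels[start:start + bs]
        probs, z = _batched_label_features(model, images, config.lsfe.reduce)
        correct = (probs >= thr) == (y == 1)
        for b in range(images.shape[0]):
            for i in range(train_set.n_labels):
                builder.admit(z[b, i], i, int(y[b, i]), bool(correct[b, i]))
    return build_pool(builder, num, seed, gamma=config.pool.gamma)


def finetune(config: Config, ckpt: Checkpoint, pool: FeaturePool | None,
             finetune_set: LabeledImageSet) -> Checkpoint:
    """Stage 2; with pool=None this is the no-pool (classification-only)
    ablation sharing the exact update trajectory of Stage 1 training."""
    model = ckpt.model
    _check_dataset(config, finetune_set, model.n_labels)
    if pool is not None:
        d = model.label_feature_dim(config.data.image_side, config.lsfe.reduce)
        if pool.dim != d:
            raise PoolError(
                f"pool dim {pool.dim} does not match model feature dim {d}")
        if list(pool.label_names) != list(finetune_set.label_names):
            raise ValidationError(
                f"pool labels {pool.label_names} do not match dataset labels "
                f"{finetune_set.label_names}")
    log = _train_loop(model, finetune_set, config, pool=pool,
                      epochs=config.train.epochs)
    return Checkpoint(model=model, config=config,
                      label_names=list(finetune_set.label_names), log=log)


# ---------------------------------------------------------------------------
# dataset utilities
# ---------------------------------------------------------------------------

def subset_dataset(dataset: LabeledImageSet, indices) -> LabeledImageSet:
    indices = np.asarray(indices)
    manifest = [dataset.manifest[int(k)] for k in indices] \
        if dataset.manifest else []
    return LabeledImageSet(images=dataset.images[indices],
                           labels=dataset.labels[indices],
                           label_names=list(dataset.label_names),
                           manifest=manifest)


def split_dataset(dataset: LabeledImageSet, fold_count: int,
                  seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive, seeded folds, stratified by label-set hash."""
    if fold_count < 2:
        raise ValidationError("fold_count must be >= 2")
    n = dataset.n_samples
    if fold_count > n:
        raise ValidationError(
            f"fold_count {fold_count} exceeds n_samples {n}")
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[int]] = {}
    for k in range(n):
        groups.setdefault(tuple(dataset.labels[k].tolist()), []).append(k)
    folds: list[list[int]] = [[] for _ in range(fold_count)]
    counter = 0
    for key in sorted(groups):
        members = np.array(groups[key])
        rng.shuffle(members)
        for m in members:
            folds[counter % fold_count].append(int(m))
            counter += 1
    return [np.array(sorted(f)) for f in folds]
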