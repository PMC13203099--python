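"""Seeded synthetic multi-label image benchmark.

Real multi-label radiograph collections have three statistical properties the
framework targets: long-tailed per-label prevalence (rare findings below 5%
positives), pairwise label co-occurrence, and a localized visual signature per
finding. This module emulates exactly those properties with parametric
phantoms: every label owns a fixed geometric motif (disc, ring, bars, checker,
cross, diamond, frame) drawn at a label-specific anchor region on a noisy
background, so an image is positive for a label if and only if its motif is
present. It makes no attempt at anatomical realism, and CheXpert-style
uncertainty labels are not emulated.

Label vectors are sampled through a Gaussian copula: latent correlated
normals are thresholded at the per-label quantile, which preserves the
requested marginal prevalences exactly while allowing controllable pairwise
positive correlation.

Defaults define the package's standard benchmark: 2000 samples, six labels
with prevalences 0.5/0.4/0.3/0.2/0.1/0.05 (all below the 25% regime, the
rarest at 5%), 64x64 images, background Normal(0.3, 0.1), motif contrast 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import norm

from .errors import ConsistencyError, FormatError, ValidationError

MOTIF_KINDS = ("disc", "ring", "hbar", "vbar", "checker", "cross",
               "diamond", "frame")

#: anchor cells on a 3x3 grid (row, col), centre cell left free, fixed order
_ANCHORS = ((0, 0), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1), (2, 2))

DEFAULT_PREVALENCE = (0.5, 0.4, 0.3, 0.2, 0.1, 0.05)


@dataclass
class SyntheticSpec:
    n_samples: int = 2000
    n_labels: int = 6
    prevalence: tuple = DEFAULT_PREVALENCE
    cooccurrence: np.ndarray | None = None
    image_size: int = 64
    noise_sd: float = 0.1
    motif_contrast: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.prevalence = tuple(float(p) for p in self.prevalence)
        if self.n_samples < 1:
            raise ValidationError("n_samples must be positive")
        if len(self.prevalence) != self.n_labels:
            raise ValidationError(
                f"prevalence has length {len(self.prevalence)}, expected "
                f"n_labels={self.n_labels}")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence):
            raise ValidationError("prevalence entries must lie in [0, 1]")
        if self.n_labels > len(MOTIF_KINDS):
            raise ValidationError(
                f"n_labels={self.n_labels} exceeds the {len(MOTIF_KINDS)} "
                "available motif kinds")
        if self.image_size < 32:
            raise ValidationError("image_size must be at least 32")
        if self.cooccurrence is not None:
            c = np.asarray(self.cooccurrence, dtype=np.float64)
            if c.shape != (self.n_labels, self.n_labels):
                raise ValidationError("cooccurrence must be N x N")
            if not np.allclose(c, c.T):
                raise ValidationError("cooccurrence must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValidationError("cooccurrence must have unit diagonal")
            if c.min() < 0.0 or c.max() > 1.0 + 1e-12:
                raise ValidationError("cooccurrence entries must lie in [0, 1]")
            self.cooccurrence = c


@dataclass
class LabeledImageSet:
    images: np.ndarray          # (n, s, s) in [0, 1]
    labels: np.ndarray          # (n, N) of {0, 1}
    label_names: list[str]
    manifest: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.images.shape[0] != self.labels.shape[0]:
            raise ConsistencyError(
                f"{self.images.shape[0]} images but {self.labels.shape[0]} "
                "label rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def motif_mask(label_index: int, image_size: int) -> np.ndarray:
    """Boolean full-image mask of label `label_index`'s motif at its anchor."""
    m = image_size // 4
    yy, xx = np.mgrid[0:m, 0:m]
    cy = cx = (m - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    kind = MOTIF_KINDS[label_index]
    if kind == "disc":
        patch = r <= 0.35 * m
    elif kind == "ring":
        patch = (r <= 0.42 * m) & (r >= 0.25 * m)
    elif kind == "hbar":
        patch = (yy >= m // 3) & (yy < 2 * m // 3)
    elif kind == "vbar":
        patch = (xx >= m // 3) & (xx < 2 * m // 3)
    elif kind == "checker":
        cell = max(1, m // 4)
        patch = ((yy // cell + xx // cell) % 2 == 0)
    elif kind == "cross":
        w = max(1, m // 6)
        patch = (np.abs(yy - cy) <= w) | (np.abs(xx - cx) <= w)
    elif kind == "diamond":
        patch = (np.abs(yy - cy) + np.abs(xx - cx)) <= 0.45 * m
    else:  # frame
        w = max(1, m // 6)
        patch = (yy < w) | (yy >= m - w) | (xx < w) | (xx >= m - w)
    row, col = _ANCHORS[label_index]
    cell_size = image_size // 3
    top = row * cell_size + (cell_size - m) // 2
    left = col * cell_size + (cell_size - m) // 2
    mask = np.zeros((image_size, image_size), dtype=bool)
    mask[top:top + m, left:left + m] = patch
    return mask


def anchor_region(label_index: int, image_size: int) -> tuple[slice, slice]:
    """Slices of the anchor patch where label `label_index`'s motif lives."""
    m = image_size // 4
    row, col = _ANCHORS[label_index]
    cell_size = image_size // 3
    top = row * cell_size + (cell_size - m) // 2
    left = col * cell_size + (cell_size - m) // 2
    return slice(top, top + m), slice(left, left + m)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _correlation_matrix(spec: SyntheticSpec) -> np.ndarray | None:
    if spec.cooccurrence is None:
        return None
    c = spec.cooccurrence.copy()
    # clip eigenvalues to keep the copula correlation positive semidefinite
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < 1e-9:
        vals = np.clip(vals, 1e-9, None)
        c = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def sample_labels(spec: SyntheticSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample the n x N binary label matrix via the Gaussian copula."""
    thresholds = norm.ppf(spec.prevalence)  # -inf for p=0, +inf for p=1
    corr = _correlation_matrix(spec)
    if corr is None:
        z = rng.standard_normal((spec.n_samples, spec.n_labels))
    else:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(spec.n_labels))
        z = rng.standard_normal((spec.n_samples, spec.n_labels)) @ chol.T
    return (z < thresholds).astype(np.int8)


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate images whose label-i positivity <=> motif i is present.

    Identical spec (including seed) reproduces byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    labels = sample_labels(spec, rng)
    masks = [motif_mask(i, spec.image_size) for i in range(spec.n_labels)]
    images = np.empty((spec.n_samples, spec.image_size, spec.image_size))
    for k in range(spec.n_samples):
        img = rng.normal(0.3, spec.noise_sd,
                         (spec.image_size, spec.image_size))
        for i in np.flatnonzero(labels[k]):
            img[masks[i]] += spec.motif_contrast
        images[k] = np.clip(img, 0.0, 1.0)
    names = [f"label_{i + 1}" for i in range(spec.n_labels)]
    manifest = [{"id": k, "file": f"img_{k:05d}.png",
                 "labels": labels[k].tolist()}
                for k in range(spec.n_samples)]
    return LabeledImageSet(images=images, labels=labels, label_names=names,
                           manifest=manifest)


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: LabeledImageSet, directory) -> Path:
    """Write PNG images, a CSV label table and a JSON manifest; returns the
    manifest path. Pixel round-trip error is bounded by 8-bit quantization."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec, img in zip(dataset.manifest, dataset.images):
        arr = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / rec["file"])
    table = pd.DataFrame(dataset.labels, columns=dataset.label_names)
    table.insert(0, "id", [rec["id"] for rec in dataset.manifest])
    table.to_csv(directory / "labels.csv", index=False)
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps({
        "label_names": dataset.label_names,
        "n_samples": dataset.n_samples,
        "image_size": int(dataset.images.shape[1]),
        "images": dataset.manifest,
    }, indent=1))
    return manifest_path


def read_dataset(directory) -> LabeledImageSet:
    directory = Path(directory)
    manifest_file = directory / "manifest.json"
    csv_file = directory / "labels.csv"
    if not manifest_file.exists() or not csv_file.exists():
        raise FormatError(f"{directory} is not a dataset directory "
                          "(missing manifest.json or labels.csv)")
    meta = json.loads(manifest_file.read_text())
    label_names = meta["label_names"]
    table = pd.read_csv(csv_file)
    missing = [c for c in ["id", *label_names] if c not in table.columns]
    if missing:
        raise FormatError(f"labels.csv is missing columns: {missing}")
    records = meta["images"]
    if len(records) != len(table):
        raise ConsistencyError(
            f"manifest lists {len(records)} images but labels.csv has "
            f"{len(table)} rows")
    images = []
    for rec in records:
        path = directory / rec["file"]
        if not path.exists():
            raise ConsistencyError(f"image file missing: {path}")
        images.append(np.asarray(Image.open(path), dtype=np.float64) / 255.0)
    labels = table[label_names].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise FormatError("labels.csv entries must be 0/1")
    return LabeledImageSet(images=np.stack(images),
                           labels=labels.astype(np.int8),
                           label_names=list(label_names),
                           manifest=records)
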