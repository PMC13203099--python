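"""Per-label positive/negative feature banks.

For each label the pool keeps a positive and a negative bank, each a fixed
Num x d matrix of representative feature vectors. Banks are built from
correctly classified training samples, brought to exactly Num rows by either
feature-space augmentation (interpolation, extrapolation, Gaussian noise —
when undersized) or K-Means condensation to Num centroids (when oversized),
and thereafter refreshed one vector at a time: a newly admitted vector
replaces the stored vector least cosine-similar to it, so capacity is
conserved and the bank tracks the target-domain distribution.

Each vector carries a provenance tag: raw | interp | extrap | noise |
centroid | update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import DataError, FormatError, PoolError, ValidationError
from .lsfe import FLATTEN_ORDER

_TAG_DTYPE = "<U8"


def _unit_rows(mat: np.ndarray, context: str) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DataError(f"zero-norm vector in {context}")
    return mat / norms


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DataError(f"zero-norm vector in {context}")
    return v / n


# ---------------------------------------------------------------------------
# bank construction primitives
# ---------------------------------------------------------------------------

def augment_bank(vectors, target: int, seed: int, gamma: float = 0.1,
                 allow_single: bool = False):
    """Expand source vectors to exactly `target` rows.

    Sources are retained in order; synthetic rows cycle through interpolation
    (lam*v1 + (1-lam)*v2), extrapolation (v1 + lam*(v1-v2)) and additive
    Gaussian noise with per-dimension scale gamma * bank SD. lam ~ Uniform(0,1).

    Returns (target x d matrix, list of provenance tags).
    """
    src = np.asarray(vectors, dtype=np.float64)
    if src.ndim != 2:
        raise ValidationError("augment_bank expects an M x d array")
    m, d = src.shape
    if m < 2 and not allow_single:
        raise PoolError(
            f"augmentation needs >= 2 source vectors, got {m} "
            "(pass allow_single=True for a noise-only fallback)")
    if m < 1:
        raise PoolError("augmentation needs at least one source vector")
    if target < m:
        raise ValidationError(f"target {target} smaller than source count {m}")
    rng = np.random.default_rng(seed)
    sd = src.std(axis=0)
    rows = [src]
    tags = ["raw"] * m
    kinds = ("interp", "extrap", "noise") if m >= 2 else ("noise",)
    new = []
    k = 0
    while m + len(new) < target:
        kind = kinds[k % len(kinds)]
        k += 1
        if kind == "noise":
            idx = rng.integers(m)
            new.append(src[idx] + rng.normal(0.0, 1.0, size=d) * gamma * sd)
        else:
            i, j = rng.choice(m, size=2, replace=False)
            lam = rng.uniform()
            if kind == "interp":
                new.append(lam * src[i] + (1.0 - lam) * src[j])
            else:
                new.append(src[i] + lam * (src[i] - src[j]))
        tags.append(kind)
    if new:
        rows.append(np.array(new))
    return np.concatenate(rows, axis=0), tags


def condense_bank(vectors, num: int, seed: int) -> np.ndarray:
    """Condense M > num vectors to num K-Means centroids (k-means++, seeded)."""
    mat = np.asarray(vectors, dtype=np.float64)
    if mat.ndim != 2:
        raise ValidationError("condense_bank expects an M x d array")
    if mat.shape[0] <= num:
        raise PoolError(
            f"condensation requires more vectors ({mat.shape[0]}) than "
            f"centroids ({num}); caller should skip condensation")
    km = KMeans(n_clusters=num, init="k-means++", n_init=1, max_iter=100,
                random_state=seed % (2 ** 31))
    km.fit(mat)
    return km.cluster_centers_.astype(np.float64)


# ---------------------------------------------------------------------------
# the pool itself
# ---------------------------------------------------------------------------

@dataclass
class FeaturePool:
    label_names: list[str]
    num: int
    dim: int
    pos: list[np.ndarray]           # per label, (num, d)
    neg: list[np.ndarray]
    pos_tags: list[list[str]]
    neg_tags: list[list[str]]
    flatten_order: str = FLATTEN_ORDER
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def bank(self, i: int, positive: bool) -> np.ndarray:
        return (self.pos if positive else self.neg)[i]

    # -- cached similarity statistics -----------------------------------

    def mean_unit(self, i: int, positive: bool) -> np.ndarray:
        """Mean of unit-normalised bank rows.

        The mean cosine similarity of a query against the whole bank equals
        the dot product of the unit query with this vector, so it is the only
        statistic the loss needs per bank.
        """
        key = ("mu", i, positive)
        if key not in self._cache:
            mat = self.bank(i, positive)
            self._cache[key] = _unit_rows(mat, f"bank[{i}]").mean(axis=0)
        return self._cache[key]

    def cross_similarity(self, i: int) -> float:
        """Mean pairwise cosine similarity between label i's two banks.

        Cached; invalidated whenever an update touches label i. The cached
        value always equals a fresh recomputation.
        """
        key = ("cross", i)
        if key not in self._cache:
            self._cache[key] = float(
                self.mean_unit(i, True) @ self.mean_unit(i, False))
        return self._cache[key]

    def _invalidate(self, i: int, positive: bool) -> None:
        self._cache.pop(("mu", i, positive), None)
        self._cache.pop(("cross", i), None)

    # -- dynamic update ---------------------------------------------------

    def update(self, z: np.ndarray, i: int, y: int) -> int:
        """Admit z into label i's bank for class y; evict the least-similar
        pre-existing vector (ties broken by lowest row index). Returns the
        evicted row index. Capacity is conserved."""
        z = np.asarray(z, dtype=np.float64)
        if not np.isfinite(z).all():
            raise DataError("non-finite feature vector passed to update")
        if z.shape != (self.dim,):
            raise PoolError(f"dim mismatch: vector has {z.shape}, pool dim {self.dim}")
        positive = bool(y)
        mat = self.bank(i, positive)
        sims = _unit_rows(mat, f"bank[{i}]") @ _unit(z, "update vector")
        evict = int(np.argmin(sims))
        mat[evict] = z
        (self.pos_tags if positive else self.neg_tags)[i][evict] = "update"
        self._invalidate(i, positive)
        return evict

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        header = {
            "label_names": self.label_names,
            "num": self.num,
            "dim": self.dim,
            "flatten_order": self.flatten_order,
        }
        arrays = {"header": np.array(json.dumps(header))}
        for i in range(self.n_labels):
            arrays[f"pos_{i}"] = self.pos[i]
            arrays[f"neg_{i}"] = self.neg[i]
            arrays[f"pos_tags_{i}"] = np.array(self.pos_tags[i], dtype=_TAG_DTYPE)
            arrays[f"neg_tags_{i}"] = np.array(self.neg_tags[i], dtype=_TAG_DTYPE)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)


def save_pool(pool: FeaturePool, path) -> None:
    pool.save(path)


def load_pool(path, expect_flatten_order: str | None = None) -> FeaturePool:
    try:
        with np.load(path, allow_pickle=False) as archive:
            header = json.loads(str(archive["header"]))
            n = len(header["label_names"])
            pos = [archive[f"pos_{i}"].astype(np.float64) for i in range(n)]
            neg = [archive[f"neg_{i}"].astype(np.float64) for i in range(n)]
            pos_tags = [list(archive[f"pos_tags_{i}"]) for i in range(n)]
            neg_tags = [list(archive[f"neg_tags_{i}"]) for i in range(n)]
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt archives raise various types
        raise FormatError(f"cannot read pool file {path}: {exc}") from exc
    num, dim = header["num"], header["dim"]
    for i in range(n):
        for mat in (pos[i], neg[i]):
            if mat.shape != (num, dim):
                raise FormatError(
                    f"bank {i} has shape {mat.shape}, header says ({num},{dim})")
    if (expect_flatten_order is not None
            and header["flatten_order"] != expect_flatten_order):
        raise FormatError(
            f"pool flatten order {header['flatten_order']!r} does not match "
            f"current configuration {expect_flatten_order!r}")
    return FeaturePool(label_names=list(header["label_names"]), num=num,
                       dim=dim, pos=pos, neg=neg, pos_tags=pos_tags,
                       neg_tags=neg_tags,
                       flatten_order=header["flatten_order"])


def update_pool(pool: FeaturePool, z, i: int, y: int) -> FeaturePool:
    """Functional alias for the dynamic single-vector update (in place)."""
    pool.update(z, i, y)
    return pool


# ---------------------------------------------------------------------------
# builder: admission during the initialization pass
# ---------------------------------------------------------------------------

class PoolBuilder:
    """Collects admitted vectors before the pool is sized and built."""

    def __init__(self, label_names: list[str], dim: int):
        self.label_names = list(label_names)
        self.dim = dim
        n = len(self.label_names)
        self.pos_vectors: list[list[np.ndarray]] = [[] for _ in range(n)]
        self.neg_vectors: list[list[np.ndarray]] = [[] for _ in range(n)]

    def admit(self, z, i: int, y: int, prediction_correct: bool) -> "PoolBuilder":
        """Store z for label i's class-y bank iff the sample was correctly
        classified for that label; misclassified samples are discarded."""
        z = np.asarray(z, dtype=np.float64)
        if z.shape != (self.dim,):
            raise PoolError(
                f"dim mismatch: vector has shape {z.shape}, builder dim {self.dim}")
        if prediction_correct:
            (self.pos_vectors if y else self.neg_vectors)[i].append(z)
        return self

    def counts(self) -> list[tuple[int, int]]:
        return [(len(p), len(q))
                for p, q in zip(self.pos_vectors, self.neg_vectors)]


def _finalize_bank(vectors: list[np.ndarray], num: int, seed: int,
                   gamma: float):
    mat = np.asarray(vectors, dtype=np.float64)
    if not np.isfinite(mat).all():
        raise DataError("non-finite admitted vector")
    m = mat.shape[0]
    if m > num:
        return condense_bank(mat, num, seed), ["centroid"] * num
    if m < num:
        return augment_bank(mat, num, seed, gamma=gamma)
    return mat.copy(), ["raw"] * num


def build_pool(builder: PoolBuilder, num: int, seed: int,
               gamma: float = 0.1) -> FeaturePool:
    """Size every bank to exactly `num` rows (condense / augment / keep)."""
    deficient = [name for name, (p, q)
                 in zip(builder.label_names, builder.counts())
                 if p < 2 or q < 2]
    if deficient:
        raise PoolError(
            "cannot build pool: labels with fewer than 2 admitted vectors in "
            f"a bank: {deficient}")
    pos, neg, pos_tags, neg_tags = [], [], [], []
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(builder.label_names))
    for i in range(len(builder.label_names)):
        mat, tags = _finalize_bank(builder.pos_vectors[i], num,
                                   int(seeds[2 * i]), gamma)
        pos.append(mat)
        pos_tags.append(tags)
        mat, tags = _finalize_bank(builder.neg_vectors[i], num,
                                   int(seeds[2 * i + 1]), gamma)
        neg.append(mat)
        neg_tags.append(tags)
    return FeaturePool(label_names=builder.label_names, num=num,
                       dim=builder.dim, pos=pos, neg=neg,
                       pos_tags=pos_tags, neg_tags=neg_tags)
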