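"""Feature-pool admission, augmentation, condensation, eviction, and I/O."""

import numpy as np
import pytest

import labelbank as lb
from labelbank.errors import DataError, FormatError, PoolError
from labelbank.pool import PoolBuilder, augment_bank, condense_bank
from conftest import random_pool


# ---------------------------------------------------------------------------
# admission
# ---------------------------------------------------------------------------

def test_admit_routes_by_label_and_correctness():
    b = PoolBuilder(["a", "b"], dim=3)
    z = np.ones(3)
    b.admit(z, 0, 1, True)
    assert [len(v) for v in b.pos_vectors] == [1, 0]
    assert [len(v) for v in b.neg_vectors] == [0, 0]
    b.admit(z, 0, 0, False)  # misclassified: discarded
    assert [len(v) for v in b.neg_vectors] == [0, 0]


def test_admission_counts_match_flag_tallies(rng):
    b = PoolBuilder(["a"], dim=4)
    flags = rng.random(100) < 0.6
    ys = rng.integers(0, 2, 100)
    for f, y in zip(flags, ys):
        b.admit(rng.normal(size=4), 0, int(y), bool(f))
    assert len(b.pos_vectors[0]) == int((flags & (ys == 1)).sum())
    assert len(b.neg_vectors[0]) == int((flags & (ys == 0)).sum())


def test_admit_dim_mismatch():
    with pytest.raises(PoolError, match="dim"):
        PoolBuilder(["a"], dim=3).admit(np.ones(4), 0, 1, True)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_interpolation_midpoint_and_extrapolation_formula():
    v1, v2 = np.array([0.0, 0.0]), np.array([2.0, 2.0])
    lam = 0.5
    np.testing.assert_array_equal(lam * v1 + (1 - lam) * v2, [1.0, 1.0])
    v1, v2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    np.testing.assert_array_equal(v1 + lam * (v1 - v2), [1.5, -0.5])


def test_augment_reaches_target_with_sources_first(rng):
    src = rng.normal(size=(3, 5))
    out, tags = augment_bank(src, 300, seed=1)
    assert out.shape == (300, 5)
    np.testing.assert_array_equal(out[:3], src)
    assert tags[:3] == ["raw"] * 3
    assert set(tags[3:]) == {"interp", "extrap", "noise"}


def test_augment_interpolants_lie_between_parents():
    """With noise disabled (gamma=0) every synthetic interp row must be an
    affine combination of two sources with weights in [0,1]."""
    src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    out, tags = augment_bank(src, 40, seed=3, gamma=0.0)
    for row, tag in zip(out, tags):
        if tag != "interp":
            continue
        best = np.inf
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                diff = src[j] - src[i]
                lam = np.clip(diff @ (row - src[i]) / (diff @ diff), 0, 1)
                best = min(best, np.linalg.norm(src[i] + lam * diff - row))
        assert best <= 1e-9


def test_augment_is_seeded_and_reproducible(rng):
    src = rng.normal(size=(4, 3))
    a, _ = augment_bank(src, 50, seed=9)
    b, _ = augment_bank(src, 50, seed=9)
    np.testing.assert_array_equal(a, b)


def test_augment_single_source_requires_opt_in():
    with pytest.raises(PoolError, match="2 source"):
        augment_bank(np.ones((1, 3)), 10, seed=0)
    out, tags = augment_bank(np.ones((1, 3)), 10, seed=0, allow_single=True)
    assert out.shape == (10, 3)
    assert set(tags[1:]) == {"noise"}


# ---------------------------------------------------------------------------
# condensation
# ---------------------------------------------------------------------------

def test_condense_recovers_two_planted_centers():
    rng = np.random.default_rng(0)
    centers = np.array([[0.0] * 4, [10.0 / np.sqrt(4)] * 4])
    pts = np.concatenate([c + rng.normal(0, 0.01, size=(30, 4))
                          for c in centers])
    cents = condense_bank(pts, 2, seed=5)
    d = np.linalg.norm(cents[:, None] - centers[None], axis=2)
    assert d.min(axis=0).max() < 0.05  # each true center recovered


def test_condense_duplicate_point_instance_reproduces_distinct_points():
    pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [0.0, 5.0]])
    cents = condense_bank(pts, 3, seed=1)
    got = sorted(map(tuple, np.round(cents, 9)))
    assert got == [(0.0, 0.0), (0.0, 5.0), (5.0, 0.0)]


def test_condense_is_deterministic(rng):
    pts = rng.normal(size=(50, 3))
    np.testing.assert_array_equal(condense_bank(pts, 5, seed=3),
                                  condense_bank(pts, 5, seed=3))


def test_condense_contract_violation():
    with pytest.raises(PoolError, match="skip"):
        condense_bank(np.ones((3, 2)), 3, seed=0)


# ---------------------------------------------------------------------------
# build
# ---------------------------------------------------------------------------

def _builder_with_counts(rng, n_pos, n_neg, dim=4):
    b = PoolBuilder(["a"], dim=dim)
    for _ in range(n_pos):
        b.admit(rng.normal(size=dim), 0, 1, True)
    for _ in range(n_neg):
        b.admit(rng.normal(size=dim), 0, 0, True)
    return b


def test_build_condenses_oversized_and_augments_undersized(rng):
    b = _builder_with_counts(rng, 500, 40)
    pool = lb.build_pool(b, 300, seed=2)
    assert pool.pos[0].shape == (300, 4)
    assert pool.neg[0].shape == (300, 4)
    assert set(pool.pos_tags[0]) == {"centroid"}
    assert pool.neg_tags[0][:40] == ["raw"] * 40
    assert set(pool.neg_tags[0][40:]) <= {"interp", "extrap", "noise"}


def test_build_exact_count_keeps_raw_vectors(rng):
    b = _builder_with_counts(rng, 5, 5)
    pool = lb.build_pool(b, 5, seed=2)
    np.testing.assert_array_equal(pool.pos[0], np.asarray(b.pos_vectors[0]))
    assert pool.pos_tags[0] == ["raw"] * 5


def test_build_names_deficient_labels(rng):
    b = PoolBuilder(["healthy", "rare"], dim=3)
    for _ in range(4):
        b.admit(rng.normal(size=3), 0, 1, True)
        b.admit(rng.normal(size=3), 0, 0, True)
        b.admit(rng.normal(size=3), 1, 0, True)
    with pytest.raises(PoolError, match="rare"):
        lb.build_pool(b, 4, seed=0)


# ---------------------------------------------------------------------------
# dynamic update
# ---------------------------------------------------------------------------

def test_update_evicts_brute_force_argmin_cosine():
    pool = lb.FeaturePool(
        label_names=["a"], num=3, dim=2,
        pos=[np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])],
        neg=[np.ones((3, 2))],
        pos_tags=[["raw"] * 3], neg_tags=[["raw"] * 3])
    z = np.array([1.0, 0.1])
    pool.update(z, 0, 1)
    rows = sorted(map(tuple, np.round(pool.pos[0], 6)))
    # (-1,0) had minimal cosine (~ -0.995) and must be gone
    assert (-1.0, 0.0) not in rows
    assert (1.0, 0.1) in rows


def test_update_on_identical_bank_preserves_multiset():
    pool = lb.FeaturePool(
        label_names=["a"], num=3, dim=2,
        pos=[np.ones((3, 2))], neg=[np.ones((3, 2))],
        pos_tags=[["raw"] * 3], neg_tags=[["raw"] * 3])
    pool.update(np.ones(2), 0, 1)
    np.testing.assert_array_equal(pool.pos[0], np.ones((3, 2)))


def test_update_capacity_and_eviction_optimality_sweep(rng):
    """Across many random updates the bank size stays Num, and every survivor
    is at least as cosine-similar to the new vector as the evictee was."""
    pool = random_pool(rng, n_labels=2, num=8, dim=5)
    for _ in range(300):
        i = int(rng.integers(2))
        y = int(rng.integers(2))
        z = rng.normal(size=5)
        before = pool.bank(i, bool(y)).copy()
        sims = before @ z / (np.linalg.norm(before, axis=1)
                             * np.linalg.norm(z))
        evicted = pool.update(z, i, y)
        assert evicted == int(np.argmin(sims))
        after = pool.bank(i, bool(y))
        assert after.shape == (8, 5)
        np.testing.assert_array_equal(after[evicted], z)
    assert all(p.shape == (8, 5) for p in pool.pos + pool.neg)


def test_update_rejects_non_finite(rng):
    pool = random_pool(rng)
    with pytest.raises(DataError):
        pool.update(np.array([np.nan] * 10), 0, 1)


def test_cached_cross_similarity_tracks_updates(rng):
    pool = random_pool(rng, n_labels=1, num=6, dim=4)
    before = pool.cross_similarity(0)
    assert pool.cross_similarity(0) == before  # cached value is stable
    pool.update(rng.normal(size=4), 0, 1)
    after = pool.cross_similarity(0)
    fresh = lb.cross_pool_similarity(pool.pos[0], pool.neg[0])
    np.testing.assert_allclose(after, fresh, atol=1e-9)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_save_load_round_trip_is_bitwise(tmp_path, rng):
    pool = random_pool(rng, n_labels=2, num=4, dim=6)
    pool.pos_tags[0][1] = "interp"
    path = tmp_path / "pool.npz"
    lb.save_pool(pool, path)
    back = lb.load_pool(path)
    for i in range(2):
        np.testing.assert_array_equal(back.pos[i], pool.pos[i])
        np.testing.assert_array_equal(back.neg[i], pool.neg[i])
        assert back.pos_tags[i] == pool.pos_tags[i]
    assert back.label_names == pool.label_names
    assert (back.num, back.dim) == (4, 6)


def test_truncated_pool_file_is_format_error(tmp_path, rng):
    path = tmp_path / "pool.npz"
    lb.save_pool(random_pool(rng), path)
    raw = path.read_bytes()
    path.write_bytes(raw[: len(raw) // 2])
    with pytest.raises(FormatError):
        lb.load_pool(path)


def test_flatten_order_mismatch_is_rejected(tmp_path, rng):
    path = tmp_path / "pool.npz"
    lb.save_pool(random_pool(rng), path)
    with pytest.raises(FormatError, match="flatten"):
        lb.load_pool(path, expect_flatten_order="h,w,c")
    assert lb.load_pool(path, expect_flatten_order="c,h,w") is not None
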