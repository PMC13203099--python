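"""Two-stage training orchestration: loops, pool lifecycle, splits."""

import copy

import numpy as np
import pytest

import labelbank as lb
from labelbank.errors import PoolError, ValidationError
from labelbank.losses import batch_contrastive
from labelbank.pool import PoolBuilder


def test_pretrain_reduces_classification_loss(pretrained):
    _, _, ckpt, _ = pretrained
    epochs = sorted({e["epoch"] for e in ckpt.log})
    first = np.mean([e["l_cls"] for e in ckpt.log if e["epoch"] == epochs[0]])
    last = np.mean([e["l_cls"] for e in ckpt.log if e["epoch"] == epochs[-1]])
    assert last < first


def test_zero_epochs_leaves_initialization_untouched(small_config,
                                                     small_dataset):
    cfg = copy.deepcopy(small_config)
    cfg.train.epochs = 0
    ckpt = lb.pretrain(cfg, small_dataset)
    fresh = lb.build_model(cfg, small_dataset.n_labels)
    for (_, a), (_, b) in zip(ckpt.model.parameters(), fresh.parameters()):
        np.testing.assert_array_equal(a.data, b.data)
    assert ckpt.log == []


def test_same_seed_reproduces_identical_training(small_config, small_dataset):
    a = lb.pretrain(copy.deepcopy(small_config), small_dataset)
    b = lb.pretrain(copy.deepcopy(small_config), small_dataset)
    assert a.log[-1]["l_cls"] == b.log[-1]["l_cls"]
    for (_, pa), (_, pb) in zip(a.model.parameters(), b.model.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


def test_label_count_mismatch_is_config_error(small_config, small_dataset):
    model = lb.build_model(small_config, 5)
    with pytest.raises(ValidationError, match="label"):
        lb.pretrain(small_config, small_dataset, model=model)


# ---------------------------------------------------------------------------
# pool initialization
# ---------------------------------------------------------------------------

def test_initialize_pool_banks_have_num_rows(pretrained):
    cfg, _, _, pool = pretrained
    assert all(p.shape == (cfg.pool.num, pool.dim)
               for p in pool.pos + pool.neg)


def test_admission_counts_under_a_stub_perfect_classifier(small_dataset):
    """If every sample is correctly classified, admitted counts equal the
    label tallies."""
    y = small_dataset.labels
    builder = PoolBuilder(list(small_dataset.label_names), dim=4)
    rng = np.random.default_rng(0)
    for k in range(small_dataset.n_samples):
        for i in range(small_dataset.n_labels):
            builder.admit(rng.normal(size=4), i, int(y[k, i]), True)
    for i, (np_, nn) in enumerate(builder.counts()):
        assert np_ == int(y[:, i].sum())
        assert nn == int((1 - y[:, i]).sum())


def test_all_negative_predictions_cause_build_error(small_config,
                                                    small_dataset):
    cfg = copy.deepcopy(small_config)
    cfg.train.epochs = 0
    ckpt = lb.pretrain(cfg, small_dataset)
    # force every logit strongly negative: no positive is ever "correct"
    ckpt.model.head.bias.data[:] = -50.0
    ckpt.model.head.weight.data[:] = 0.0
    with pytest.raises(PoolError, match="fewer than 2"):
        lb.initialize_pool(ckpt, small_dataset)


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def test_finetune_rejects_pool_dim_mismatch(pretrained):
    cfg, dataset, ckpt, pool = pretrained
    bad = copy.deepcopy(pool)
    bad.dim = pool.dim + 1
    bad.pos = [np.pad(p, ((0, 0), (0, 1))) for p in bad.pos]
    bad.neg = [np.pad(p, ((0, 0), (0, 1))) for p in bad.neg]
    with pytest.raises(PoolError, match="dim"):
        lb.finetune(cfg, copy.deepcopy(ckpt), bad, dataset)


def test_contrastive_gradient_flows_only_through_query_vector(rng):
    """Bank vectors are constants: perturbing the pool between forward and
    backward must not change the gradient of the query."""
    from labelbank.autodiff import Tensor
    from conftest import random_pool
    pool = random_pool(rng, n_labels=2, num=5, dim=6)
    z = rng.normal(size=(1, 2, 6))
    y = np.array([[1.0, 0.0]])
    t = Tensor(z, requires_grad=True)
    align, margin, _, _ = batch_contrastive(t, pool, y)
    (align.sum() + margin.sum()).backward()
    g = t.grad.copy()

    # finite-difference through the scalar surface
    def loss_at(zmod):
        total = 0.0
        for i in range(2):
            dp = lb.pool_similarity(zmod[0, i], pool.pos[i])
            dn = lb.pool_similarity(zmod[0, i], pool.neg[i])
            dc = lb.cross_pool_similarity(pool.pos[i], pool.neg[i])
            total += lb.align_loss(dp, dn, int(y[0, i]))
            total += lb.margin_loss(dp, dn, dc, int(y[0, i]))
        return total

    eps = 1e-6
    for idx in [(0, 0, 0), (0, 1, 3), (0, 0, 5)]:
        zp, zm = z.copy(), z.copy()
        zp[idx] += eps
        zm[idx] -= eps
        fd = (loss_at(zp) - loss_at(zm)) / (2 * eps)
        assert g[idx] == pytest.approx(fd, abs=1e-5)


def test_disabling_contrastive_terms_matches_cls_only_trajectory(pretrained):
    cfg, dataset, ckpt, pool = pretrained
    cfg_off = copy.deepcopy(cfg)
    cfg_off.loss.align_weight = 0.0
    cfg_off.loss.margin_weight = 0.0
    cfg_off.train.epochs = 1
    a = lb.finetune(cfg_off, copy.deepcopy(ckpt), copy.deepcopy(pool), dataset)
    cfg_cls = copy.deepcopy(cfg_off)
    b = lb.finetune(cfg_cls, copy.deepcopy(ckpt), None, dataset)
    for (_, pa), (_, pb) in zip(a.model.parameters(), b.model.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    for ea, eb in zip(a.log, b.log):
        assert ea["l_cls"] == pytest.approx(eb["l_cls"], abs=1e-7)


def test_finetune_preserves_capacity_and_updates_only_on_correct_events(
        pretrained):
    cfg, dataset, ckpt, pool = pretrained
    cfg = copy.deepcopy(cfg)
    cfg.train.epochs = 1
    pool = copy.deepcopy(pool)
    before = {(i, s): pool.bank(i, s).copy()
              for i in range(pool.n_labels) for s in (True, False)}
    out = lb.finetune(cfg, copy.deepcopy(ckpt), pool, dataset)
    assert all(p.shape == (cfg.pool.num, pool.dim)
               for p in pool.pos + pool.neg)
    n_updates = sum(e["pool_updates"] for e in out.log)
    assert n_updates > 0
    # every changed row is tagged as an update; unchanged rows keep old tags
    changed = 0
    for i in range(pool.n_labels):
        for s in (True, False):
            diff = np.any(pool.bank(i, s) != before[(i, s)], axis=1)
            tags = np.array((pool.pos_tags if s else pool.neg_tags)[i])
            assert set(tags[diff]) <= {"update"}
            changed += int(diff.sum())
    assert 0 < changed <= n_updates


def test_stage2_objective_decomposition_holds_at_every_step(pretrained):
    cfg, dataset, ckpt, pool = pretrained
    cfg = copy.deepcopy(cfg)
    cfg.train.epochs = 1
    out = lb.finetune(cfg, copy.deepcopy(ckpt), copy.deepcopy(pool), dataset)
    for e in out.log:
        assert e["l_final"] == pytest.approx(
            e["l_cls"] + e["l_align"] + e["l_margin"], abs=1e-6)


def test_epoch_granularity_updates_are_deferred(pretrained):
    cfg, dataset, ckpt, pool = pretrained
    cfg = copy.deepcopy(cfg)
    cfg.train.epochs = 1
    cfg.pool.update_every = "epoch"
    pool = copy.deepcopy(pool)
    out = lb.finetune(cfg, copy.deepcopy(ckpt), pool, dataset)
    # all updates are attributed to the final step of the epoch
    assert all(e["pool_updates"] == 0 for e in out.log[:-1])
    assert out.log[-1]["pool_updates"] > 0


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def test_checkpoint_save_load_round_trip(tmp_path, pretrained):
    _, _, ckpt, _ = pretrained
    path = tmp_path / "model.npz"
    lb.save_checkpoint(path, ckpt)
    back = lb.load_checkpoint(path)
    assert back.label_names == ckpt.label_names
    for (_, a), (_, b) in zip(ckpt.model.parameters(),
                              back.model.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_is_disjoint_exhaustive_and_balanced(small_dataset):
    folds = lb.split_dataset(small_dataset, 5, seed=3)
    all_idx = np.concatenate(folds)
    assert len(all_idx) == small_dataset.n_samples
    assert len(np.unique(all_idx)) == small_dataset.n_samples
    sizes = [len(f) for f in folds]
    assert max(sizes) - min(sizes) <= 1


def test_split_is_seeded(small_dataset):
    a = lb.split_dataset(small_dataset, 4, seed=9)
    b = lb.split_dataset(small_dataset, 4, seed=9)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)


def test_split_stratifies_rare_positives_when_feasible():
    labels = np.zeros((50, 1), dtype=np.int8)
    labels[:10, 0] = 1
    ds = lb.LabeledImageSet(images=np.zeros((50, 32, 32)), labels=labels,
                            label_names=["only"])
    folds = lb.split_dataset(ds, 5, seed=1)
    for f in folds:
        assert labels[f, 0].sum() >= 1


def test_split_fold_count_validation(small_dataset):
    with pytest.raises(ValidationError):
        lb.split_dataset(small_dataset, 1, seed=0)
    with pytest.raises(ValidationError):
        lb.split_dataset(small_dataset, small_dataset.n_samples + 1, seed=0)
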