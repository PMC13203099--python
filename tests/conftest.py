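import numpy as np
import pytest

import labelbank as lb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but learnable synthetic set (32px to keep tests fast)."""
    spec = lb.SyntheticSpec(n_samples=160, n_labels=3,
                            prevalence=(0.5, 0.3, 0.1),
                            image_size=32, seed=11)
    return lb.generate_dataset(spec)


@pytest.fixture
def small_config():
    cfg = lb.Config()
    cfg.seed = 7
    cfg.data.image_side = 32
    cfg.train.epochs = 2
    cfg.train.batch_size = 32
    cfg.pool.num = 12
    return cfg


@pytest.fixture(scope="session")
def pretrained():
    """Stage-1 checkpoint + pool on the small dataset, shared across tests."""
    cfg = lb.Config()
    cfg.seed = 7
    cfg.data.image_side = 32
    cfg.train.epochs = 12
    cfg.train.batch_size = 32
    cfg.pool.num = 12
    spec = lb.SyntheticSpec(n_samples=160, n_labels=3,
                            prevalence=(0.5, 0.3, 0.1),
                            image_size=32, seed=11)
    dataset = lb.generate_dataset(spec)
    ckpt = lb.pretrain(cfg, dataset)
    pool = lb.initialize_pool(ckpt, dataset)
    return cfg, dataset, ckpt, pool


def random_pool(rng, n_labels=3, num=6, dim=10, names=None):
    """A well-formed random pool for loss/update tests."""
    names = names or [f"label_{i + 1}" for i in range(n_labels)]
    return lb.FeaturePool(
        label_names=names, num=num, dim=dim,
        pos=[rng.normal(size=(num, dim)) for _ in range(n_labels)],
        neg=[rng.normal(size=(num, dim)) for _ in range(n_labels)],
        pos_tags=[["raw"] * num for _ in range(n_labels)],
        neg_tags=[["raw"] * num for _ in range(n_labels)])
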