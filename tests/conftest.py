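import numpy as np
import pytest

from veinid.data import (SplitSpec, SyntheticVeinConfig,
                         generate_synthetic_dataset, split_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic set shared by data/pipeline tests."""
    cfg = SyntheticVeinConfig(n_identities=6, images_per_identity=6,
                              n_sessions=2, roi_size=(40, 120), seed=7)
    return generate_synthetic_dataset(cfg)


def randomize_bn(bn, rng):
    """Give a batch-norm layer non-trivial frozen statistics."""
    bn.gamma.data = rng.normal(1.0, 0.2, bn.num_features).astype(bn.gamma.dtype)
    bn.beta.data = rng.normal(0.0, 0.2, bn.num_features).astype(bn.beta.dtype)
    bn.running_mean = rng.normal(0.0, 0.5, bn.num_features)
    bn.running_var = rng.uniform(0.5, 2.0, bn.num_features)


def randomize_dbb(dbb, rng):
    for bn in (dbb.bn_kxk, dbb.bn_1x1, dbb.seq_bn1, dbb.seq_bn2,
               dbb.avg_bn1, dbb.avg_bn2):
        randomize_bn(bn, rng)
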