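import numpy as np
import pytest

from psychae import SCENARIOS, generate, study_structures
from psychae.grid import derive_seed

MASTER_SEED = 20210


@pytest.fixture(scope="session")
def structures():
    return study_structures()


@pytest.fixture(scope="session")
def high_split_2000(structures):
    """A fixed high-communality normal dataset split 80/20 and z-scored."""
    from psychae import standardize_apply, standardize_fit

    seed = derive_seed(MASTER_SEED, "high-2000")
    dataset = generate(structures["high"], SCENARIOS["s1"], 2000, seed)
    rng = np.random.default_rng(derive_seed(seed, "split"))
    perm = rng.permutation(2000)
    test_idx, train_idx = perm[:400], perm[400:]
    scaler = standardize_fit(dataset.data[train_idx])
    train = standardize_apply(scaler, dataset.data[train_idx])
    test = standardize_apply(scaler, dataset.data[test_idx])
    return train, test
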