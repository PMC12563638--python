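import numpy as np
import pytest

from fuzzent.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Four-subject synthetic dataset shared by feature/eval/CLI tests."""
    cfg = SimConfig(n_subjects=4, n_trials_per_condition=10, seed=7)
    return cfg, generate_dataset(cfg)
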