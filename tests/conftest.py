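import numpy as np
import pytest

import jointirt as j


@pytest.fixture(scope="session")
def small_truth():
    """A small constant-speed dataset with stored truth."""
    return j.simulate_joint_data(150, 12, seed=42)


@pytest.fixture(scope="session")
def small_fit_ident2(small_truth):
    cfg = j.MCMCConfig(n_iter=400, seed=7, ident=2)
    return j.fit_joint_model(small_truth.data, cfg)


@pytest.fixture(scope="session")
def small_fit_ident1(small_truth):
    cfg = j.MCMCConfig(n_iter=400, seed=7, ident=1)
    return j.fit_joint_model(small_truth.data, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
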