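import warnings

import numpy as np
import pytest

from cisel import TargetSpec, gen_glm


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    """Model-fit warnings (iteration limits, separation notices from the
    statistical backends) are noise in bulk simulation tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def gaussian_ds():
    """300 x 20 continuous dataset with 3 strong planted features."""
    return gen_glm(300, 20, family="gaussian", n_active=3, beta=1.0, seed=11)


@pytest.fixture
def null_target(rng):
    return TargetSpec(rng.standard_normal(200), "continuous")
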