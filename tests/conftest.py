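import warnings

import numpy as np
import pytest

from cogproxy.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """21 sites, ~4-7 families each: fast enough for fold-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(default_config(seed=11, scale=0.03))


@pytest.fixture(scope="session")
def small_cohort():
    """~600 baseline participants: enough signal for pipeline sanity checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(default_config(seed=7, scale=0.12))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
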