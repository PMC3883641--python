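import dataclasses

import numpy as np
import pytest

from ssbtax.synthetic import default_ground_truth, generate_households


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def clean_truth(truth):
    """Noise-free, censoring-free variant of the packaged ground truth."""
    st = dataclasses.replace(truth.settings, share_noise_sd=0.0,
                             consume_prob={})
    return dataclasses.replace(truth, settings=st)


@pytest.fixture(scope="session")
def households_10k(truth):
    """Moderate sample with the default noise and censoring settings."""
    return generate_households(10_000, truth, seed=11)


@pytest.fixture(scope="session")
def p_ref(truth):
    from ssbtax.tables import GOODS
    return np.array([truth.settings.median_prices[g] for g in GOODS])
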