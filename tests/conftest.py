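from __future__ import annotations

import numpy as np
import pytest

import misstrial as mt


@pytest.fixture(scope="session")
def default_cohort():
    """Trial-sized cohort (n=1758) from the default generative config."""
    config = mt.default_iquit_config()
    records, shadow = mt.generate_cohort(config, seed=424)
    return records, shadow, config


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for Monte-Carlo comparisons against the generative model."""
    config = mt.default_iquit_config(n=80000)
    records, shadow = mt.generate_cohort(config, seed=77)
    return records, shadow, config


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
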