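import warnings

import numpy as np
import pytest

from bamphy.simulate import DEFAULT_TAXA, SimConfig


@pytest.fixture(autouse=True)
def _quiet_saturation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="saturated pair")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20160520)


@pytest.fixture
def small_config():
    """A 6-taxon, 20-gene configuration for fast end-to-end checks."""
    return SimConfig(seed=42, n_genes=20, taxa=DEFAULT_TAXA[:6])


@pytest.fixture
def noise_free_config():
    return SimConfig(
        seed=7, n_genes=15, taxa=DEFAULT_TAXA[:6],
        paralogue_rate=0.0, variant_rate=0.0,
    )
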