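import numpy as np
import pytest

from spotsim import ScenarioConfig, build_template_bank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast 20-person scenario used across integration-level tests."""
    return ScenarioConfig(
        biological_half_life=4.0,
        n_individuals=20,
        window_days=7,
        max_samples=7,
        seed=7,
    )


@pytest.fixture
def bank(rng):
    return build_template_bank(8, 6, rng)
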