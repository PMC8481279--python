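import numpy as np
import pytest

from social_diffusion import (
    EXPLORER_PARAMS,
    NONEXPLORER_PARAMS,
    PopulationSpec,
    SimulationConfig,
    TrialGeneratorConfig,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """n=200, 25% committed minority, one fifth explorers."""
    return PopulationSpec(n=200, committed_count=50, rho_e=0.2)


@pytest.fixture
def fast_config():
    return SimulationConfig(max_steps=5_000, seed=7)


@pytest.fixture(scope="session")
def clean_dataset():
    """20 synthetic trials with no irregular behaviour injected."""
    cfg = TrialGeneratorConfig(
        n_participants=None,
        dropout_rate=0.0,
        missed_round_rate=0.0,
        stubborn_rate=0.0,
    )
    return generate_dataset(20, cfg, seed=2024)


@pytest.fixture(scope="session")
def realistic_dataset():
    """20 synthetic trials at the default irregularity rates."""
    return generate_dataset(20, TrialGeneratorConfig(n_participants=None), seed=99)
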