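import numpy as np
import pytest

from fusesurv.datagen import SimulationConfig, simulate_cohort
from fusesurv.encoder import EncoderConfig


@pytest.fixture(scope="session")
def small_cohort():
    """150-sample cohort with moderate effects and ~30% censoring."""
    cfg = SimulationConfig(
        n_samples=150,
        n_genes=40,
        n_programs=3,
        beta_programs=(1.0, 0.6, -0.5),
        beta_clinical=(0.4, 0.2, 0.5),
        censoring_target=0.3,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return EncoderConfig(vocab_size=12, hidden_width=6, n_layers=3,
                         pool_type="max", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
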