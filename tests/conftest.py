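import numpy as np
import pytest

from plastex.synthetic import SimConfig, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_experiment():
    """One small synthetic experiment shared across read-only tests."""
    cfg = SimConfig(n_genes=300, seed=42)
    counts, designs, truth = simulate_experiment(cfg)
    return cfg, counts, designs, truth
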