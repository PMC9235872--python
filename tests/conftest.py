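import numpy as np
import pytest

from oryzamix.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def three_group_dataset():
    """Small three-group dataset with clear separation, shared across tests."""
    cfg = SimulationConfig(n_accessions=90, n_snps=200, n_traits=5,
                           n_groups_true=3, group_separation=6.0,
                           replicate_count=3, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def single_gaussian_means():
    """Accession means drawn from one Gaussian (no group structure)."""
    rng = np.random.default_rng(123)
    return rng.standard_normal((200, 5))
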