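import numpy as np
import pytest

from epibind.synthetic import SimConfig, latent_bin_matrices


@pytest.fixture(scope="session")
def small_latent():
    """300-anchor latent matrices for bins +1 and +40, with ground truth."""
    cfg = SimConfig(n_genes=300)
    mats, truth = latent_bin_matrices(cfg, master_seed=7, bins=[1, 40])
    return cfg, mats, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
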