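import numpy as np
import pytest

from eimspec import SimConfig, generate_pairs

# compact model dimensions used throughout the unit tests; defaults of the
# config dataclasses (the full-scale architecture sizes) are exercised by the
# configuration-fidelity tests instead
DESK_PARAMS = dict(
    hidden_dim=32, embedding_dim=32, qkv_dim=32, block_hidden_dim=64,
    head1_dim=64, head2_dim=32, proj_hidden_dim=64, proj_embedding_dim=32,
)


@pytest.fixture(scope="session")
def small_dataset():
    """~60 synthetic molecule–spectrum pairs, deterministic."""
    cfg = SimConfig(n_molecules=64, seed=3)
    smiles, spectra = generate_pairs(cfg)
    Y = np.stack([s.intensities for s in spectra])
    return smiles, spectra, Y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
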