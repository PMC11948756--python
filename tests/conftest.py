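import numpy as np
import pytest

from idpchar import synth


@pytest.fixture
def zero_noise():
    return synth.NoiseSpec(sigma=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture(scope="session")
def hdx_table_clean():
    """Noiseless synthetic HDX flat table with the default protection truth."""
    return synth.gen_hdx_dataset(noise=synth.NoiseSpec(0.0, 7))


@pytest.fixture(scope="session")
def hdx_table_noisy():
    return synth.gen_hdx_dataset(noise=synth.NoiseSpec(0.02, 7))
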