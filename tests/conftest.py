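import numpy as np
import pytest

from dmdc import gen_limit_cycle, gen_torus


@pytest.fixture(scope="session")
def limit_cycle_epoch():
    """Noiseless 10 Hz sine, 2500 samples at 1 kHz: period 100 samples."""
    return gen_limit_cycle(n=2500, fs=1000.0, freq=10.0, seed=3)


@pytest.fixture(scope="session")
def torus_epoch():
    """Two-tone quasiperiodic signal on a 2-torus, 10000 samples."""
    return gen_torus(n=10000, fs=1000.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
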