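import numpy as np
import pytest

import breathescan as bs


@pytest.fixture(scope="session")
def params():
    return bs.ModelParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_chain():
    seq = bs.PromoterSequence(id="toy", bases="ATATGCGCATATATGCAT")
    return bs.encode(seq, clamp_len=3)


@pytest.fixture(scope="session")
def compiled_kernel(params):
    """Force numba compilation once per session on a tiny system."""
    seq = bs.PromoterSequence(id="warm", bases="ATGC")
    chain = bs.encode(seq, clamp_len=1)
    cfg = bs.SimulationConfig(dt=0.05, n_steps=10, preheat_steps=0,
                              n_realizations=1, sample_stride=5, seed=0)
    bs.run_realization(chain, params, cfg, 0)
    return True
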