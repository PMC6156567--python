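import numpy as np
import pytest

from kemplab.synthetic import gen_rate_data, gen_toy_evb_system


@pytest.fixture(scope="session")
def noiseless_rates():
    """Rate table generated without noise: fits must recover truth exactly."""
    return gen_rate_data(seed=0, noise=0.0)


@pytest.fixture(scope="session")
def noisy_rates():
    return gen_rate_data(seed=1, noise=0.02)


@pytest.fixture(scope="session")
def gas_triad():
    """Solute-only (no waters) donor–H–acceptor system."""
    return gen_toy_evb_system(seed=1, n_waters=0)


@pytest.fixture(scope="session")
def small_droplet():
    """A few waters: big enough to exercise solvent terms, fast to run."""
    sys_ = gen_toy_evb_system(seed=5, n_waters=5, shake_waters=False)
    # conservative cutoff covering the whole droplet: no cutoff
    # discontinuities in conservation checks
    sys_.cutoff = 2.0 * sys_.droplet_radius
    sys_._build_pairlists()
    return sys_


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
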