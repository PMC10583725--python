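import numpy as np
import pytest

from cgaim.synthetic import SimulationScenario, gen_three_index, three_index_spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Three-index data with no noise (n=1000)."""
    return gen_three_index(SimulationScenario(n=1000, sigma=0.0, seed=3))


@pytest.fixture(scope="session")
def noisy_sim():
    """Three-index data at the middle noise level (n=1000, sigma=0.5)."""
    return gen_three_index(SimulationScenario(n=1000, sigma=0.5, seed=11))


@pytest.fixture(scope="session")
def cgaim_spec():
    return three_index_spec("cgaim")


@pytest.fixture(scope="session")
def noisy_fit(noisy_sim, cgaim_spec):
    from cgaim import fit_cgaim

    return fit_cgaim(cgaim_spec, noisy_sim["data"])
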