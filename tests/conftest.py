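import numpy as np
import pytest

from polymap import simulate as sim


@pytest.fixture(scope="session")
def tetra_clean():
    """Small clean tetraploid data set with known truth (m=4)."""
    rng = np.random.default_rng(42)
    parents = sim.simulate_parents(4, 10, 27.0, seed=rng)
    truth = sim.simulate_population(parents, 150, seed=rng)
    obs = sim.observe_dosages(truth, error_rate=0.0, seed=rng)
    return parents, truth, obs


@pytest.fixture(scope="session")
def hexa_clean():
    """Clean hexaploid data set with known truth (m=6)."""
    rng = np.random.default_rng(7)
    parents = sim.simulate_parents(6, 12, 33.0, seed=rng)
    truth = sim.simulate_population(parents, 200, seed=rng)
    obs = sim.observe_dosages(truth, error_rate=0.0, seed=rng)
    return parents, truth, obs
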