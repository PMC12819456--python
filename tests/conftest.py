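import numpy as np
import pytest

from covertfnirs import SimulationParams, default_montage, simulate_subject


@pytest.fixture(scope="session")
def probe():
    return default_montage()


def small_params(**kw) -> SimulationParams:
    """A shortened acquisition (1 block x 4 reps, ~130 s) for fast unit tests."""
    defaults = dict(n_blocks=1, reps_per_block=4, inter_block_gap=0.0,
                    lead_in=10.0, seed=0)
    defaults.update(kw)
    return SimulationParams(**defaults)


@pytest.fixture(scope="session")
def small_responder():
    return simulate_subject(small_params(seed=11, hbo_amplitude=1.0))


@pytest.fixture(scope="session")
def small_null():
    return simulate_subject(small_params(seed=12, hbo_amplitude=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
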