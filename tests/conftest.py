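import numpy as np
import pytest

import gainfield as gf

SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def default_grid():
    """The full hardwired lattice with the standard parameter set."""
    return gf.build_population()


_TRAINED: dict = {}


@pytest.fixture(scope="session")
def trained():
    """Memoized access to fully trained networks, keyed by (seed, rho).

    Training a network takes tens of seconds, and several tests probe the
    same trained populations; the cache keeps each (seed, rho) run unique
    per session.
    """

    def get(seed: int, rho: float):
        key = (seed, float(rho))
        if key not in _TRAINED:
            _TRAINED[key] = gf.train_network(seed, rho=float(rho))
        return _TRAINED[key]

    return get


@pytest.fixture()
def small_schedule_config():
    """A short schedule (1 epoch, 3 locations, 4 fixations) for fast runs."""
    return gf.TrainingConfig(
        epochs=1,
        retinal_range=(-1.0, 1.0),
        fixations_per_period=4,
    )


@pytest.fixture()
def small_network():
    layer = gf.default_input_layer()
    net = gf.init_network(0, layer, n_outputs=20)
    return net, layer
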