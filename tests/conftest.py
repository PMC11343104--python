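import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_obs(rng):
    """Six random observations of a smooth 1-D function at distinct times."""
    from hilopt.gp import ObservationSet

    x = rng.uniform(-3.0, 3.0, 6)
    t = np.arange(6)
    y = np.sin(x) + rng.normal(0.0, 0.05, 6)
    return ObservationSet(x[:, None], t, y)
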