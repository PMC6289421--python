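import numpy as np
import pytest

import cohortme as cm
from cohortme.io import example_model, random_model


@pytest.fixture(scope="session")
def example_cfg():
    return example_model()


@pytest.fixture(scope="session")
def example_Q(example_cfg):
    return example_cfg.generator()


@pytest.fixture(scope="session")
def two_state():
    """2-state model with a single decay channel c12 = 0.3."""
    states = cm.StateSpace(["S1", "S2"])
    Q = cm.build_generator(states, {("S1", "S2"): 0.3})
    return states, Q


@pytest.fixture
def random_generators():
    """A batch of seed-reproducible random generator matrices."""
    def make(n, s_range=(2, 5), rate_scale=0.3):
        out = []
        for i in range(n):
            rng = np.random.default_rng(1000 + i)
            s = int(rng.integers(*s_range))
            out.append(random_model(s, seed=1000 + i, rate_scale=rate_scale).generator())
        return out
    return make
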