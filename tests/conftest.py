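import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_two_group():
    """A small two-group dataset with a few shifted genes."""
    import rbm

    cfg = rbm.ScenarioConfig(m=40, n=6, pi1=0.25, B=50, seed=11)
    return rbm.generate_dataset(cfg, 0)
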