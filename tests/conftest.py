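import numpy as np
import pytest
from hypothesis import settings

from arraymelt.parameters import default_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from arraymelt.synthdata import random_gene


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def gene():
    """A 16S-sized random target gene, fixed across the session."""
    rng = np.random.default_rng(20120827)
    return random_gene(rng, 1542, 0.54)
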