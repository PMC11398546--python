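import numpy as np
import pytest
from hypothesis import settings

import symrep as sr

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_planted():
    """3-fiber planted graph, sizes (2, 3, 2)."""
    return sr.generate_fibered_graph(3, (2, 3, 2), base_density=0.6, seed=1)


@pytest.fixture(scope="session")
def study():
    """The reference synthetic study: 7-fiber graph + 8-animal cohort."""
    graph, cohort, config = sr.standard_synthetic_study(seed=1)
    return graph, cohort, config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
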