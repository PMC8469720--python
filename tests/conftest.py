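import numpy as np
import pytest

from stwinscan.seqcore import IntronModel
from stwinscan.synth import SimParams, TemplateParams, build_genome, make_template


@pytest.fixture(scope="session")
def model():
    return IntronModel()


@pytest.fixture(scope="session")
def template42(model):
    """Default ancestral template, fixed seed."""
    return make_template(TemplateParams(), model, 42)


@pytest.fixture(scope="session")
def sim_genome(model):
    """Small synthetic genome with all planted categories, fixed seed."""
    return build_genome(SimParams(seed=2021, divergence=(0.0, 0.10)), model)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
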