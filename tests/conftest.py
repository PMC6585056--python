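import numpy as np
import pytest

from tadlink import GeneratorConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset, planted truth attached."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
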