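import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from saltshift import packaged_scenario
from saltshift.synthetic import GeneratorConfig, generate_model_inputs


@pytest.fixture(scope="session")
def desk():
    """Desk-preset initial population and parameter bundle (fixed seed)."""
    return generate_model_inputs(GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def scenarios():
    """The two packaged policy scenarios and their shared SBP effect model."""
    s1, effect = packaged_scenario("scenario1")
    s2, _ = packaged_scenario("scenario2")
    return s1, s2, effect


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
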