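import hypothesis
import numpy as np
import pytest

from cometddr import GeneratorParams, generate_invivo_study

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture(scope="session")
def small_invivo():
    """Reduced in vivo study (2 doses, 20 nucleoids/gel) for pipeline tests."""
    params = GeneratorParams(doses=(0.0, 0.5), n_nucleoids=20)
    return generate_invivo_study(params, seed=11)


@pytest.fixture(scope="session")
def full_invivo():
    return generate_invivo_study(GeneratorParams(), seed=42)
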