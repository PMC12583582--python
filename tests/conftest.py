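import pytest

from soilrisk import GeneratorSpec, ParameterRegistry, generate_survey


@pytest.fixture(scope="session")
def registry() -> ParameterRegistry:
    return ParameterRegistry()


@pytest.fixture(scope="session")
def small_survey():
    """A seeded 53-sample synthetic survey shared across integration tests."""
    return generate_survey(GeneratorSpec(n_samples=53, seed=20240907))
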