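import pytest
from hypothesis import HealthCheck, settings

import sibscreen as sb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_params() -> sb.ParameterSet:
    """Shipped base-case parameter set."""
    return sb.load_parameters()


@pytest.fixture(scope="session")
def config() -> sb.ModelConfig:
    return sb.default_config()


@pytest.fixture(scope="session")
def societal(config) -> sb.Perspective:
    return config.perspective("societal")


@pytest.fixture(scope="session")
def life_table() -> sb.LifeTable:
    return sb.bundled_life_table()


@pytest.fixture(scope="session")
def strategies(base_params):
    return {s.label: s for s in sb.default_strategies(base_params)}
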