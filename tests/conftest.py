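import pytest
from hypothesis import HealthCheck, settings

from lipidce import default_parameters, generate_life_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life():
    return generate_life_table()
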