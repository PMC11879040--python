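import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from toxtoolbox import GeneratorConfig, generate_benchmark, load_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The packaged 38-chemical / 70-scenario benchmark decision fixture."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def synthetic_benchmark():
    """A default-condition synthetic benchmark with its ground truth."""
    return generate_benchmark(GeneratorConfig(seed=1))
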