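import pytest

from sroikit import GeneratorSpec, calvary_fixture, generate_suite


@pytest.fixture
def calvary():
    return calvary_fixture()


@pytest.fixture(scope="session")
def scenario_suite():
    """100 seeded synthetic scenarios shared by the property tests."""
    return generate_suite(GeneratorSpec(seed=1000), count=100)
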