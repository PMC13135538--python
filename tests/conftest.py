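import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    from radonpreg import default_library

    return default_library()


@pytest.fixture(scope="session")
def params():
    from radonpreg import default_parameters

    return default_parameters()


@pytest.fixture(scope="session")
def params_stable():
    """No decay, sealed (vent off): closed system for conservation checks."""
    from radonpreg import default_parameters

    return default_parameters().without_ventilation().with_decay(0.0)
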