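import pytest

from atmcurate import (
    RestrictionMatrix,
    load_atm_domain_map,
    load_atm_transcript,
    load_default_constants,
)


@pytest.fixture(scope="session")
def constants():
    return load_default_constants()


@pytest.fixture(scope="session")
def transcript():
    return load_atm_transcript()


@pytest.fixture(scope="session")
def domain_map():
    return load_atm_domain_map()


@pytest.fixture(scope="session")
def matrix():
    return RestrictionMatrix.load_default()
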