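import pytest
from hypothesis import settings as hypothesis_settings

from sarcoma_cea import load_country

hypothesis_settings.register_profile("stable", derandomize=True, deadline=None)
hypothesis_settings.load_profile("stable")


@pytest.fixture(scope="session")
def italy():
    return load_country("italy")


@pytest.fixture(scope="session")
def spain():
    return load_country("spain")


@pytest.fixture(scope="session")
def sweden():
    return load_country("sweden")


@pytest.fixture(scope="session")
def all_countries(italy, spain, sweden):
    return {"italy": italy, "spain": spain, "sweden": sweden}
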