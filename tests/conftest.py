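import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phonalign.costs import default_cost_model, make_simple_cost_model
from phonalign.features import default_feature_table
from phonalign.lexicon import bundled_lexicon


@pytest.fixture(scope="session")
def features():
    return default_feature_table()


@pytest.fixture(scope="session")
def model():
    return default_cost_model()


@pytest.fixture(scope="session")
def simple_model():
    return make_simple_cost_model()


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()
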