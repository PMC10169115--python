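import pytest
from hypothesis import HealthCheck, settings

from taxdiff import derive_taxonomy, fig1_excerpt, fig2_fig3_pair

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def process_excerpt():
    return fig1_excerpt()

@pytest.fixture(scope="session")
def process_taxonomy(process_excerpt):
    return derive_taxonomy(process_excerpt)


@pytest.fixture(scope="session")
def vaccine_pair():
    return fig2_fig3_pair()


@pytest.fixture(scope="session")
def vaccine_old(vaccine_pair):
    return vaccine_pair[0]


@pytest.fixture(scope="session")
def vaccine_new(vaccine_pair):
    return vaccine_pair[1]
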