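import hypothesis
import pytest

import ssbtax as st
from ssbtax.cea import SAMPLED_FIELDS

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_spec():
    return st.SynthSpec(seed=1, mode="fixture")


@pytest.fixture(scope="session")
def schedule(fixture_spec):
    return st.generate_epi_schedule(fixture_spec)


@pytest.fixture(scope="session")
def profiles(fixture_spec):
    return st.generate_quintile_profiles(fixture_spec)


@pytest.fixture(scope="session")
def population(fixture_spec):
    return st.generate_population(fixture_spec)


@pytest.fixture(scope="session")
def params():
    return st.default_parameters()


@pytest.fixture(scope="session")
def params_degenerate(params):
    """Central values with every sampling spread set to zero."""
    return params.with_(**{f"sd_{name}": 0.0 for name in SAMPLED_FIELDS})


@pytest.fixture()
def settings_10y():
    return st.ModelSettings(horizon_years=10, n_psa_draws=50, seed=7)
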