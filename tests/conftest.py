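import logging

import pytest
from hypothesis import HealthCheck, settings

from npiplus.fuzzy import default_rulebase
from npiplus.ihc import build_cutoff_table
from npiplus.pipeline import _profiles
from npiplus.synthetic import GeneratorConfig, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# activation-tie warnings from stray synthetic marker values are expected noise
logging.getLogger("npiplus.fuzzy").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort used across integration tests."""
    return generate(GeneratorConfig(n_patients=1000, seed=17))


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    return _profiles(default_cohort.data)


@pytest.fixture(scope="session")
def default_cutoffs(default_profiles):
    return build_cutoff_table(default_profiles)


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()
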