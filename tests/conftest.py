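import pytest
from hypothesis import settings, HealthCheck

import acrytrend as at

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def all_studies():
    return at.load_all_studies()


@pytest.fixture(scope="session")
def fixture_panel(all_studies):
    panel, exclusions = at.harmonize(all_studies)
    return panel, exclusions


@pytest.fixture(scope="session")
def ns_aama_panel(fixture_panel):
    """The reconstructed non-smoker AAMA yearly-mean panel."""
    panel, _ = fixture_panel
    return at.select_panel(panel, at.Analyte.AAMA, at.Smoking.NONSMOKER)
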