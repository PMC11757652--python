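import pytest
from hypothesis import HealthCheck, settings

from actinon.reports import run_analysis
from actinon.sessions import Timepoint, load_packaged_campaign

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def campaign():
    """The packaged measurement campaign (21 administrations)."""
    return load_packaged_campaign()


@pytest.fixture(scope="session")
def report(campaign):
    """Default-configuration analysis of the packaged campaign."""
    return run_analysis(campaign)


@pytest.fixture(scope="session")
def late_report(report):
    return report.timepoints[Timepoint.LATE]


@pytest.fixture(scope="session")
def early_report(report):
    return report.timepoints[Timepoint.EARLY]
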