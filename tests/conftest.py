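import hypothesis
import pytest

from brscore import osteoarthritis_scenario

hypothesis.settings.register_profile(
    "suite",
    max_examples=100,
    derandomize=True,
    deadline=None,
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def oa_fixture():
    """Packaged osteoarthritis worked example (whole-patient counting)."""
    return osteoarthritis_scenario()


@pytest.fixture(scope="session")
def oa_scenario(oa_fixture):
    return oa_fixture.scenario


@pytest.fixture(scope="session")
def oa_fractional(oa_scenario):
    """Same assumptions and weights, exact fractional expected counts."""
    return oa_scenario.replace(whole_patients=False)
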