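import pytest

from linkededit.fixtures import build_fixture_cohort, fixture_phase_calls
from linkededit.genotyping import genotype_cohort
from linkededit.synthetic_data import make_reference


@pytest.fixture(scope="session")
def genome():
    return make_reference(seed=1)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged synthetic 32-founder cohort, built on a seed-1 reference."""
    return build_fixture_cohort(seed=1)


@pytest.fixture(scope="session")
def fixture_reports(fixture_cohort):
    g, founders = fixture_cohort
    return genotype_cohort(g, founders)


@pytest.fixture(scope="session")
def fixture_phases(fixture_cohort):
    _, founders = fixture_cohort
    return fixture_phase_calls(founders)
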