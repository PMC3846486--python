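import pytest

from wpiptyper import load_scheme
from wpiptyper.fixtures import cohort_profiles, make_cohort


@pytest.fixture(scope="session")
def scheme():
    return load_scheme()


@pytest.fixture(scope="session")
def table1_records(scheme):
    return make_cohort("table1", scheme, seed=1)


@pytest.fixture(scope="session")
def table1_profiles(scheme, table1_records):
    return cohort_profiles(table1_records, scheme)
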