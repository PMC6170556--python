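import pytest

from aircloud import build_standard_set, default_grading_table, load_shenyang_november
from aircloud.io import load_monthly_cloud_fixture


@pytest.fixture(scope="session")
def table():
    return default_grading_table()


@pytest.fixture(scope="session")
def standards(table):
    return build_standard_set(table, k=0.1)


@pytest.fixture(scope="session")
def november():
    """Shenyang November 2016 daily table (30 days)."""
    return load_shenyang_november()


@pytest.fixture(scope="session")
def monthly_fixture():
    """Published monthly cloud characteristics and levels, 12 months."""
    return load_monthly_cloud_fixture()
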