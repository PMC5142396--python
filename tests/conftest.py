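import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from secscreen.io import (  # noqa: E402
    HOST_BS,
    HOST_CG,
    load_reference_panel,
    load_campaign_table,
    campaign_sp_records,
)


@pytest.fixture(scope="session")
def campaign_table():
    return load_campaign_table()


@pytest.fixture(scope="session")
def cg_records():
    """Un-normalized C. glutamicum series from the packaged activity table."""
    return campaign_sp_records(HOST_CG)


@pytest.fixture(scope="session")
def bs_records():
    """Un-normalized B. subtilis series from the packaged activity table."""
    return campaign_sp_records(HOST_BS)


@pytest.fixture(scope="session")
def panel():
    """Packaged synthetic reference panel (NprE separated, AmyE/YwmC overlapping)."""
    return load_reference_panel()
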