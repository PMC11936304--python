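import pytest

from mhealthecon import HealthcareCostParams, default_ledger


@pytest.fixture(scope="session")
def trial_ledger():
    """Packaged trial expenditure ledger for 60 participants (2022 US $)."""
    return default_ledger(n_participants=60)


@pytest.fixture(scope="session")
def hc_params():
    """Default annual health-care cost parameters (H = 36,917)."""
    return HealthcareCostParams()
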