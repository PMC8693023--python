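import pytest

import hearcost as hc


@pytest.fixture(scope="session")
def malindi_ledger() -> hc.CostLedger:
    """The 2018 Malindi program ledger with the derived P-R+H scenario."""
    ledger = hc.load_ledger(hc.packaged_fixture("malindi_2018.csv"))
    return hc.add_no_resident_variant(ledger)


@pytest.fixture(scope="session")
def malindi_cascade() -> hc.CascadeRecord:
    """155 screened, 32 screen failures, severities 23/1/2/3/3."""
    return hc.load_cascade(hc.packaged_fixture("malindi_cascade.csv"))
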