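import pytest

import pdst


@pytest.fixture(scope="session")
def reference_table() -> pdst.PAITable:
    return pdst.load_reference_table()


@pytest.fixture(scope="session")
def reference_risk():
    return pdst.load_reference_risk()


@pytest.fixture(scope="session")
def risk_df(reference_table):
    return pdst.compute_risk_table(reference_table)


@pytest.fixture(scope="session")
def risk_by_name(reference_table):
    return {r.pai_name: r for r in pdst.risk_results(reference_table)}
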