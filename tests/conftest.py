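import pytest

from uhc_feasim.reference import price_list
from uhc_feasim.revenue import FundAllocation


@pytest.fixture(scope="session")
def prices():
    return price_list()


@pytest.fixture(scope="session")
def alloc():
    return FundAllocation()
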