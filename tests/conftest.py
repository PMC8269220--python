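import pytest

from ecophys.refdata import load_species_table


@pytest.fixture(scope="session")
def species_table():
    return load_species_table()
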