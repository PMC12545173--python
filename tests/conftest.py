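import pytest

from misokit import energetics


@pytest.fixture(scope="session")
def species_table():
    return energetics.load_species_table()


@pytest.fixture(scope="session")
def reaction1():
    return energetics.PRESET_REACTIONS["reaction1"]
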