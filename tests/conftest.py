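import pytest

from silvocarbon import load_default_ranges, load_epoch_table


@pytest.fixture(scope="session")
def epoch_tables():
    return {e: load_epoch_table(e) for e in ("1929", "1954", "2024")}


@pytest.fixture(scope="session")
def density_ranges():
    return load_default_ranges()
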