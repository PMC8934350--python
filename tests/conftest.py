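import pytest

from levyrisk import complete_rows, load_reference_table


@pytest.fixture(scope="session")
def reference_table():
    """The packaged 15-tissue parameter table."""
    return load_reference_table()


@pytest.fixture(scope="session")
def complete_table(reference_table):
    """The 8 tissues with stem-cell demography and observed risk."""
    return complete_rows(reference_table)
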