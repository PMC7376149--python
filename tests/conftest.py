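import pytest

from mrnet.sumstats import (
    load_fixture,
    load_instrument_table,
    orient_to_decrease,
    records_from_instrument_table,
)


@pytest.fixture(scope="session")
def instrument_table():
    """Bundled European LTL/ALS instrument table (numeric columns verbatim)."""
    return load_instrument_table()


@pytest.fixture(scope="session")
def ltl_records(instrument_table):
    """LTL-side association records for the 7 European instruments."""
    return records_from_instrument_table(instrument_table, trait="LTL")


@pytest.fixture(scope="session")
def als_records(instrument_table):
    return records_from_instrument_table(instrument_table, trait="ALS")


@pytest.fixture(scope="session")
def ltl_als():
    """Harmonized 7-instrument LTL/ALS set, orientation as published."""
    return load_fixture("eur_ltl_als")


@pytest.fixture(scope="session")
def ltl_als_decrease(ltl_als):
    """Same set oriented per SD decrease of LTL."""
    return orient_to_decrease(ltl_als)


@pytest.fixture(scope="session")
def paths_table():
    """Exposure->mediator->outcome path coefficients for all triples."""
    return load_fixture("eur_paths_table5")
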