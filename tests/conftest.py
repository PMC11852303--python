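from pathlib import Path

import pandas as pd
import pytest

import spreadquant as sq

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def florida_zones():
    return sq.load_florida_zones()


@pytest.fixture(scope="session")
def florida_records():
    return sq.load_florida_species()


@pytest.fixture(scope="session")
def florida_table(florida_records, florida_zones):
    return sq.build_species_table(florida_records, florida_zones)


@pytest.fixture(scope="session")
def table1_expected():
    """Published derived columns for the 31 Florida species."""
    return pd.read_csv(DATA / "table1_expected.csv")
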