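import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from anacat.composition import parse_formula
from anacat.synthetic_data import make_toy_network
from anacat.thermo import default_formation_table


@pytest.fixture(scope="session")
def table():
    return default_formation_table()


@pytest.fixture(scope="session")
def yeast_biomass():
    return parse_formula("CH1.79O0.57N0.15", label="yeast biomass")


@pytest.fixture(scope="session")
def glucose_cmol():
    return parse_formula("C6H12O6").normalize_per_cmol()


@pytest.fixture()
def ferm_resp():
    return make_toy_network("fermentation-respiration")


@pytest.fixture()
def biomass_toy():
    return make_toy_network("biomass-toy")
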