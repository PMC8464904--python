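import numpy as np
import pytest

from crystalcontacts import (
    UnitCell,
    load_reference_bcp_table,
    load_reference_contacts,
    load_reference_energies,
)
from crystalcontacts.synthetic import (
    PBAR1_OPS,
    CrystalSpec,
    PlantedContact,
    make_toy_crystal,
)


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_bcp_table()


@pytest.fixture(scope="session")
def reference_energies():
    return load_reference_energies()


@pytest.fixture(scope="session")
def reference_contacts():
    return load_reference_contacts()


@pytest.fixture(scope="session")
def brbr_crystal():
    """Toy crystal planting an inversion-related Br...Br Type I contact."""
    spec = CrystalSpec(cell=UnitCell(14, 15, 16, 90, 95, 90),
                       symop_codes=PBAR1_OPS,
                       planted=(PlantedContact("X...X", 3.525, 169.6),),
                       name="toy-brbr")
    return make_toy_crystal(spec, seed=0)


@pytest.fixture(scope="session")
def nho_crystal():
    """Toy crystal planting the double N-H...O amide ring across inversion."""
    spec = CrystalSpec(cell=UnitCell(14, 15, 16, 90, 95, 90),
                       symop_codes=PBAR1_OPS,
                       planted=(PlantedContact("N-H...O", 1.92),),
                       name="toy-nho")
    return make_toy_crystal(spec, seed=0)


@pytest.fixture(scope="session")
def empty_crystal():
    """Toy crystal with no short intermolecular contacts."""
    spec = CrystalSpec(cell=UnitCell(20, 20, 20), symop_codes=PBAR1_OPS,
                       planted=(), name="toy-empty")
    return make_toy_crystal(spec, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20210909)
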