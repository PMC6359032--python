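import numpy as np
import pytest

from reactikit.core_io import AtomRecord, MoleculeGeometry
from reactikit.igm import AtomicDensityModel, load_density_model


@pytest.fixture(scope="session")
def toy_h_model():
    """Single-shell test density: rho_el(r) = 0.2 exp(-2 r)."""
    return AtomicDensityModel({"H": [(0.2, 2.0)]})


@pytest.fixture(scope="session")
def default_model():
    return load_density_model()


def make_pair(d_bohr, elements=("H", "H")):
    """Two atoms on the x axis separated by d_bohr (positions given in Å)."""
    from reactikit.units import BOHR_TO_ANGSTROM

    a = AtomRecord(elements[0], np.zeros(3), 1)
    b = AtomRecord(elements[1], np.array([d_bohr * BOHR_TO_ANGSTROM, 0.0, 0.0]), 2)
    return MoleculeGeometry("pair", [a, b])


@pytest.fixture
def h2_pair_2bohr():
    return make_pair(2.0)
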