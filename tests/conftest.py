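import numpy as np
import pandas as pd
import pytest

from ppepkit.library import NON_PRIME_DESIGN, PRIME_DESIGN, VARIABLE_ALPHABET
from ppepkit.simulate import (
    IonizationModel,
    MODEL_POSITIONS,
    SpecificityModel,
    default_specificity_model,
)

# Independent residue-mass oracle, typed by hand from the standard IUPAC
# monoisotopic table (kept separate from the package's pyteomics-backed
# table on purpose).
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565


def oracle_mass(sequence: str) -> float:
    """Brute-force residue-mass summation, independent of ppepkit.chem."""
    return sum(ORACLE_RESIDUE_MASS[c] for c in sequence) + ORACLE_WATER


@pytest.fixture(scope="session")
def designs():
    return (NON_PRIME_DESIGN, PRIME_DESIGN)


@pytest.fixture(scope="session")
def default_model():
    return default_specificity_model()


@pytest.fixture(scope="session")
def unit_ionization():
    return IonizationModel(response_factor={})


@pytest.fixture(scope="session")
def uniform_model():
    eff = pd.DataFrame(
        1.0, index=list(VARIABLE_ALPHABET), columns=list(MODEL_POSITIONS)
    )
    return SpecificityModel(efficiency=eff)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
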