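import numpy as np
import pytest

from sunqsar import load_sunscreens, load_toy_smiles
from sunqsar.synthetic import SyntheticConfig, generate

#: Printed predictions for the 16 sunscreen queries (per-model pIC50 and
#: their means), frozen for regression against the shipped equation.
PRINTED_PREDICTIONS = {
    #        MLR    ANN1   SVR    Mean1  Mean2
    "BMDM": (4.95, 4.52, 4.83, 4.77, 4.82),
    "BP-3": (4.19, 4.15, 4.09, 4.14, 4.18),
    "DHHB": (5.57, 4.97, 5.37, 5.30, 5.27),
    "PABA": (4.48, 5.10, 4.66, 4.75, 4.87),
    "EHDP": (1.30, 3.27, 1.42, 2.00, 2.77),
    "Et-PABA": (2.79, 3.64, 2.90, 3.11, 3.45),
    "PBSA": (2.90, 3.64, 2.80, 3.11, 3.54),
    "MBC": (3.76, 3.57, 3.78, 3.70, 3.64),
    "EHMC": (2.07, 3.34, 2.12, 2.51, 3.05),
    "IMC": (2.47, 3.39, 2.50, 2.79, 3.20),
    "OCR": (6.13, 5.78, 5.91, 5.94, 5.96),
    "ET": (13.82, 14.82, 12.94, 13.86, 10.70),
    "OS": (1.24, 3.27, 1.34, 1.95, 2.75),
    "HMS": (3.50, 3.51, 3.49, 3.50, 3.57),
    "DOBT": (12.14, 13.28, 11.40, 12.27, 9.90),
    "BZ-4": (3.12, 3.70, 3.00, 3.27, 3.65),
}


@pytest.fixture(scope="session")
def sunscreens():
    return load_sunscreens()


@pytest.fixture(scope="session")
def toy_smiles():
    return load_toy_smiles()


@pytest.fixture(scope="session")
def reference121():
    """Default synthetic reference set at the demo seed."""
    return generate(SyntheticConfig(n=121, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
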