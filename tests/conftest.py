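import numpy as np
import pytest

from amideiso import datasets


BLOCKS = [("trans", "gas"), ("trans", "water"), ("cis", "gas"), ("cis", "water")]

STERIC_TABLE_NAMES = {
    ("trans", "gas"): "steric_trans_gas",
    ("trans", "water"): "steric_trans_water",
    ("cis", "gas"): "steric_cis_gas",
    ("cis", "water"): "steric_cis_water",
}


@pytest.fixture()
def model():
    """Additivity model with increments derived from packaged small-molecule energies."""
    return datasets.build_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240925)


def canonical(code_with_suffix: str) -> str:
    """Strip the t/c suffix and normalize the prime to ASCII."""
    return code_with_suffix[:-1].replace("’", "'")
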