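import numpy as np
import pytest

from probiosurf.surface_classifier import ClassifierParams
from probiosurf.synthetic_data import SyntheticProteomeSpec, generate_proteome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def default_params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def small_labeled_proteome():
    """300-protein synthetic proteome with planted surface constructs."""
    spec = SyntheticProteomeSpec(
        n_proteins=300,
        frac_secreted=0.06,
        frac_lipoprotein=0.01,
        frac_lpxtg=0.01,
        seed=42,
    )
    return generate_proteome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
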