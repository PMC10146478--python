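import logging

import numpy as np
import pytest

from virtualcontrols.data import load_reference_norms, load_reference_weights
from virtualcontrols.norm_model import NormTable
from virtualcontrols.synthetic_data import default_family_table, default_true_weights

logging.disable(logging.WARNING)  # matching exclusions are noisy in bulk tests


@pytest.fixture(scope="session")
def reference_norms() -> NormTable:
    """The packaged three-percentile published sample table."""
    return load_reference_norms()


@pytest.fixture(scope="session")
def reference_weights():
    """Published logistic weights for alcohol, drunkenness, vaping."""
    return load_reference_weights()


@pytest.fixture(scope="session")
def family_table() -> NormTable:
    """The synthetic generator's curve family on the default 198-point grid."""
    return default_family_table()


@pytest.fixture(scope="session")
def true_weights():
    return default_true_weights()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)
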