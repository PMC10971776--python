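import numpy as np
import pytest

from graphmhc.featurize import featurize_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_labelled_samples():
    """A handful of small featurized MHC/peptide pairs with labels."""
    pairs = [
        ("GAS", "GGG", 1),
        ("GAS", "AAA", 0),
        ("CVW", "GAG", 1),
        ("CVW", "SSS", 0),
        ("GAS", "ASA", 1),
        ("CVW", "VVV", 0),
    ]
    return [featurize_pair(m, p, label=y) for m, p, y in pairs]
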