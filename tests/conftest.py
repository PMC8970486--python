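import numpy as np
import pytest

from afsource import cylinder_vest, default_corpus
from afsource.features import feature_matrices
from afsource.sobss import LagSet


@pytest.fixture(scope="session")
def vest():
    return cylinder_vest()


@pytest.fixture(scope="session")
def lags():
    return LagSet()


@pytest.fixture(scope="session")
def corpus():
    """The default seeded study corpus (5 virtual patients, ~400 episodes)."""
    return default_corpus(seed=1)


@pytest.fixture(scope="session")
def corpus_features(corpus):
    """CL/MaxAC feature matrices of the corpus over the K grid {2, 4, 6}."""
    return feature_matrices(corpus.signals, [2, 4, 6])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
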