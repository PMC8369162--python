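import numpy as np
import pytest

import aophmm
from aophmm import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sequences():
    return [
        aophmm.ProteinSequence("p1", "ACDE"),
        aophmm.ProteinSequence("p2", "WWWW"),
        aophmm.ProteinSequence("p3", "ACDEFGHIKLMNPQRSTVWY"),
    ]


def random_hmm_matrix(rng, L):
    """Uniform [0,1] profile matrix of length L."""
    return rng.uniform(0.0, 1.0, size=(L, 20))


@pytest.fixture
def small_two_class_table(rng):
    """40 samples x 8 features; features 0-1 carry a strong mean shift."""
    n_per = 20
    X = rng.standard_normal((2 * n_per, 8))
    X[:n_per, :2] += 3.0
    labels = np.array(["AOP"] * n_per + ["non-AOP"] * n_per)
    return aophmm.FeatureTable(
        X=X,
        names=[f"f{i}" for i in range(8)],
        ids=[f"s{i}" for i in range(2 * n_per)],
        labels=labels,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard strong-signal fixture encoded at G=10 (shared: ~1 s)."""
    spec = syn.default_planted_spec(seed=1)
    profiles, labels = syn.make_profiles(spec)
    table = aophmm.encode_dataset(profiles, labels, scheme="acc", G=10)
    return spec, profiles, labels, table
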