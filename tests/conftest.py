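import numpy as np
import pytest

from raacfam import (
    FeatureSpec,
    SimulationConfig,
    builtin_type33,
    generate,
    get_type33,
    identity_scheme,
)


@pytest.fixture(scope="session")
def type33():
    return builtin_type33()


@pytest.fixture(scope="session")
def scheme15():
    return get_type33(15)


@pytest.fixture(scope="session")
def scheme2():
    return get_type33(2)


@pytest.fixture(scope="session")
def identity():
    return identity_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic two-class dataset for fast model-level tests."""
    config = SimulationConfig(
        n_pos=30, n_neg=30, length_range=(60, 120), seed=11, positive_bias=0.5
    )
    pos, neg, manifest = generate(config)
    records = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return records, labels, manifest


@pytest.fixture(scope="session")
def small_fasta(tmp_path_factory):
    """Tiny simulated FASTA pair on disk."""
    from raacfam import generate_dataset

    out = tmp_path_factory.mktemp("fasta")
    config = SimulationConfig(
        n_pos=20, n_neg=20, length_range=(60, 120), seed=21, positive_bias=0.5
    )
    pos_path, neg_path, truth = generate_dataset(config, out)
    return pos_path, neg_path, truth


def random_protein(rng, length):
    from raacfam.alphabet import CANONICAL

    return "".join(rng.choice(list(CANONICAL), size=length))
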