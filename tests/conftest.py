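import numpy as np
import pytest

from epofs import ClassifierSpec, SyntheticSpec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def knn_spec():
    return ClassifierSpec("knn")


@pytest.fixture(scope="session")
def tiny_dataset():
    """10-gene two-class dataset with 3 informative genes, small enough for
    exhaustive subset enumeration."""
    return generate(SyntheticSpec(
        n_instances=60, n_genes=10, n_classes=2,
        n_informative=3, n_redundant=0, effect_size=2.0, seed=3,
    ))


@pytest.fixture(scope="session")
def planted_dataset():
    """500-gene two-class dataset with 10 planted informative genes."""
    return generate(SyntheticSpec(
        n_instances=100, n_genes=500, n_classes=2,
        n_informative=10, n_redundant=0, effect_size=2.0, seed=42,
    ))


@pytest.fixture(scope="session")
def blobs_dataset():
    """Well-separated dataset every learner should classify almost perfectly."""
    return generate(SyntheticSpec(
        n_instances=200, n_genes=20, n_classes=2,
        n_informative=10, n_redundant=0, effect_size=4.0, seed=7,
    ))
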