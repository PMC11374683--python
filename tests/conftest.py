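import numpy as np
import pytest

from pepdesign import models, seqdata, synthetic


@pytest.fixture(scope="session")
def landscape():
    return synthetic.make_landscape(synthetic.make_landscape_spec(seed=1))


@pytest.fixture(scope="session")
def dataset(landscape):
    ds, _ = synthetic.sample_training_set(landscape, n=125, seed=1)
    return ds


@pytest.fixture(scope="session")
def tiny_spec():
    """A very small network configuration for fast structural tests."""
    return models.ModelSpec.reduced(
        conv_filters=(4, 8, 4), dense=(8, 4), max_epochs=40, patience=15,
        seed=11)


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_spec, dataset):
    X = seqdata.encode_batch(dataset.peptides)
    Y = dataset.labels()
    return models.train_ensemble(
        tiny_spec, X[:100], Y[:100], X[100:110], Y[100:110], M=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
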