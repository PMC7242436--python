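import numpy as np
import pytest

from mixehr import ModelHyperparameters, initialize_state, make_fixture


@pytest.fixture(scope="session")
def fixture():
    """The fixed tiny corpus plus its ground truth."""
    return make_fixture()


@pytest.fixture(scope="session")
def fixture_corpus(fixture):
    return fixture[0]


@pytest.fixture()
def hyper2(fixture_corpus):
    return ModelHyperparameters.symmetric(
        2, fixture_corpus.type_sizes, fixture_corpus.lab_sizes
    )


@pytest.fixture()
def state2(fixture_corpus):
    """A seeded K=2 variational state on the fixture."""
    return initialize_state(fixture_corpus, 2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
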