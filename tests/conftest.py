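import numpy as np
import pytest

from deepquartet import (FragmentScoreTable, PriorHyperparams, train_prior,
                         make_smiles_corpus, make_toy_pharmacophore)
from deepquartet.synthetic import CorpusSpec


@pytest.fixture(scope="session")
def corpus_small():
    """400-molecule grammar corpus for vocabulary / SA / scaffold tests."""
    return make_smiles_corpus(CorpusSpec(n=400, seed=11))


@pytest.fixture(scope="session")
def sa_table(corpus_small):
    return FragmentScoreTable.from_corpus(corpus_small)


@pytest.fixture(scope="session")
def small_prior():
    """Briefly trained small prior for RL mechanics tests (~10 s)."""
    corpus = make_smiles_corpus(CorpusSpec(n=800, seed=2))
    hp = PriorHyperparams(epochs=6, hidden_size=64, batch_size=64,
                          learning_rate=5e-3)
    return train_prior(corpus, hp, seed=0)


@pytest.fixture(scope="session")
def trained_prior():
    """Well-trained prior (hidden 128) for validity and full-loop tests."""
    corpus = make_smiles_corpus(CorpusSpec(n=3000, seed=2))
    hp = PriorHyperparams(epochs=25, hidden_size=128, batch_size=64,
                          learning_rate=5e-3)
    return train_prior(corpus, hp, seed=0)


@pytest.fixture(scope="session")
def toy_pharm():
    return make_toy_pharmacophore(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
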