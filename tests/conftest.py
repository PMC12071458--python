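"""Shared fixtures: the synthetic corpus and a scaled-down trained model.

The corpus (2,000 molecules, seed 42) and the 30-epoch K=8 training run are
session-scoped because several test modules interrogate the same trained
model; everything is generated programmatically at test time.
"""

import numpy as np
import pytest

from icvae.fixtures import FixtureSpec, generate_corpus
from icvae.model import ICVAE, ModelConfig
from icvae.trainer import TrainConfig, train

CORPUS_SEED = 42
TOY_TRAIN_CONFIG = dict(
    seed=42,
    epochs=30,
    batch_size=4,
    learning_rate=1e-3,
    K=8,
    conditioned_properties=("HBA",),
)


@pytest.fixture(scope="session")
def fixture_corpus():
    """(corpus, property table) for the standard 2,000-molecule fixture."""
    return generate_corpus(FixtureSpec(n=2000, seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def trained_toy(fixture_corpus):
    """The scaled-down study model: K=8, HBA-conditioned, 30 epochs, seed 42."""
    corpus, table = fixture_corpus
    return train(TrainConfig(**TOY_TRAIN_CONFIG), corpus, table)


@pytest.fixture(scope="session")
def untrained_toy(trained_toy):
    """The untrained counterpart on the exact init-seed path of the toy run."""
    init_seed = int(
        np.random.SeedSequence(TOY_TRAIN_CONFIG["seed"]).spawn(3)[1].generate_state(1)[0]
        % (2**31)
    )
    config = trained_toy.model.config
    return ICVAE(config, seed=init_seed)
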