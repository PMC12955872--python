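"""Shared fixtures: a synthetic training corpus and a classifier trained on
it, built once per session because LM training is the slow step."""

import pytest

from mbfus.mlp import TrainConfig, split_and_undersample, train_mlp
from mbfus.subject import generate_training_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default-parameter constant-pressure corpus, 20 subjects x 4 targets."""
    return generate_training_corpus(20, seed=11)


@pytest.fixture(scope="session")
def train_cfg():
    return TrainConfig(seed=5, restarts=2, epochs=400)


@pytest.fixture(scope="session")
def split_sets(corpus, train_cfg):
    return split_and_undersample(corpus, train_cfg)


@pytest.fixture(scope="session")
def trained_mlp(split_sets, train_cfg):
    train_set, _ = split_sets
    return train_mlp(train_set, train_cfg)
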