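import numpy as np
import pytest

from riddle import (
    GeneNetwork,
    GeneSet,
    SvmParams,
    corpus_features,
    make_training_corpus,
    synthetic_network,
    train_combiner,
)

# fixed seeds so every run exercises the same synthetic world
WORLD_SEED = 11
CORPUS_SEED = 12
TRAIN_SEED = 13


@pytest.fixture
def path3() -> GeneNetwork:
    """A - B - C with unit weights."""
    return GeneNetwork([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def two_components() -> GeneNetwork:
    """Two disconnected edges: A1-A2 and B1-B2."""
    return GeneNetwork([("A1", "A2", 1.0), ("B1", "B2", 1.0)])


def gene_set(*members: str, sid: str = "s") -> GeneSet:
    return GeneSet(id=sid, name=sid, members=frozenset(members))


@pytest.fixture(scope="session")
def default_world():
    return synthetic_network(seed=WORLD_SEED)


@pytest.fixture(scope="session")
def trained(default_world):
    """Combiner trained on the default world's simulated corpus."""
    rng = np.random.default_rng(CORPUS_SEED)
    positives, negatives = make_training_corpus(default_world, rng=rng)
    cache: dict = {}
    x_pos = corpus_features(default_world, positives, profile_cache=cache)
    x_neg = corpus_features(default_world, negatives, profile_cache=cache)
    model, report = train_combiner(x_pos, x_neg, SvmParams(), seed=TRAIN_SEED)
    return model, report
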