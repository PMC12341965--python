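import numpy as np
import pytest

import synlogic as sl


@pytest.fixture
def toy_network() -> sl.PriorKnowledgeNetwork:
    """Two mutually activating nodes plus an inhibitor loop."""
    return sl.build_network([
        sl.SignedInteraction("A", "B", 1),
        sl.SignedInteraction("B", "A", 1),
        sl.SignedInteraction("C", "B", -1),
        sl.SignedInteraction("B", "C", 1),
    ])


@pytest.fixture
def canonical_network() -> sl.PriorKnowledgeNetwork:
    """Node T with three activators and three inhibitors, all loop-closed."""
    edges = [sl.SignedInteraction(s, "T", 1) for s in "ABC"]
    edges += [sl.SignedInteraction(s, "T", -1) for s in "DEF"]
    edges += [sl.SignedInteraction("T", s, 1) for s in "ABCDEF"]
    return sl.build_network(edges)


@pytest.fixture
def small_system() -> sl.PlantedSystem:
    return sl.generate_planted_system(rng=np.random.default_rng(1),
                                      unique_optimum=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
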