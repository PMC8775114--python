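import numpy as np
import pytest

from dermprio import (
    DEFAULT_PRIORITIES,
    DEFAULT_TAXONOMY,
    default_knowledge_map,
    load_count_table,
)


@pytest.fixture(scope="session")
def km():
    return default_knowledge_map()


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def priorities():
    return DEFAULT_PRIORITIES


@pytest.fixture(scope="session")
def test1_counts():
    return load_count_table(partition="test1")


@pytest.fixture(scope="session")
def test2_counts():
    return load_count_table(partition="test2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
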