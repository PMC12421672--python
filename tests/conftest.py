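import pytest
from hypothesis import settings

from molannotate.fixtures import (
    fixed_corpus_size,
    seed_hierarchy,
    seed_pattern_collection,
    toy_corpus,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

CORPUS_SEED = 7
CORPUS_SIZE = 200


@pytest.fixture(scope="session")
def seed_collection():
    return seed_pattern_collection()


@pytest.fixture(scope="session")
def hierarchy():
    return seed_hierarchy()


@pytest.fixture(scope="session")
def corpus():
    """The fixed-seed 200-molecule toy corpus."""
    return toy_corpus(seed=CORPUS_SEED, n=CORPUS_SIZE - fixed_corpus_size())
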