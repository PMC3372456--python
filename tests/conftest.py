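import pytest

from termassoc.io import TopicRecord
from termassoc.query import extract_keywords
from termassoc.synthetic import SyntheticSpec, generate_collection

TOPIC_200_DESCRIPTION = (
    "What serum [PROTEINS] change expression in association with high "
    "disease activity in lupus?"
)


@pytest.fixture(scope="session")
def topic_200():
    return TopicRecord("200", TOPIC_200_DESCRIPTION)


@pytest.fixture(scope="session")
def topic_200_keywords(topic_200):
    return extract_keywords(topic_200)


@pytest.fixture(scope="session")
def small_collection():
    """A small neutral synthetic collection (no planted structure)."""
    return generate_collection(SyntheticSpec(n_docs=40), seed=11)
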