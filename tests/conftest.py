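"""Shared fixtures: curated example documents and seeded synthetic corpora."""

from __future__ import annotations

import pytest

from bbct.examples import load_curated_examples
from bbct.fixtures import FixtureConfig, generate_corpus
from bbct.syntax import analyze


@pytest.fixture(scope="session")
def curated():
    """Curated example documents keyed by id."""
    return {doc.doc_id: doc for doc in load_curated_examples()}


@pytest.fixture(scope="session")
def curated_parsed(curated):
    """Parsed (gold CoNLL-U backend) versions of the curated documents."""
    return {doc_id: analyze(doc) for doc_id, doc in curated.items()}


@pytest.fixture(scope="session")
def synthetic_corpus():
    """One seeded synthetic corpus covering every template twice."""
    return generate_corpus(FixtureConfig(seed=7, n_docs=26))


@pytest.fixture(scope="session")
def synthetic_parsed(synthetic_corpus):
    return [analyze(doc) for doc in synthetic_corpus]
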