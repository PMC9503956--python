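"""Shared fixtures: a synthetic corpus, template library and trained potential.

Everything is generated programmatically at session start; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from dna3d.fixtures import default_corpus, generate_corpus
from dna3d.optimization import train_potential
from dna3d.template_library import build_library

CORPUS_SEED = 0


@pytest.fixture(scope="session")
def corpus_specs():
    return default_corpus(CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus(corpus_specs):
    """(source_id, Structure, DotBracket, resolution) records."""
    return generate_corpus(corpus_specs)


@pytest.fixture(scope="session")
def corpus_by_name(corpus):
    return {name: (s, db) for name, s, db, _ in corpus}


@pytest.fixture(scope="session")
def seq_by_name(corpus_specs):
    return {sp.name: sp.seq for sp in corpus_specs}


@pytest.fixture(scope="session")
def library(corpus):
    return build_library(corpus)


@pytest.fixture(scope="session")
def energy_model(corpus):
    return train_potential([s for _, s, _, _ in corpus])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
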