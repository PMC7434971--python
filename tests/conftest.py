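import logging

import numpy as np
import pytest

from textphase.corpus_prep import build_binary_matrix, lemmatize, rank_and_select_lemmas
from textphase.synthetic_data import SimParams, generate_corpus

logging.getLogger("textphase").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """A fast small-corpus configuration used by several suites."""
    return SimParams(n_docs=40, vocab_size=200, n_factors=5,
                     doc_length_range=(20, 80), shift_index=20,
                     polarization_pre=0.5, polarization_post=49.0, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_params):
    return generate_corpus(small_params)


@pytest.fixture(scope="session")
def small_matrix(small_corpus):
    corpus, _ = small_corpus
    streams = lemmatize(corpus)
    selected = rank_and_select_lemmas(streams)
    return build_binary_matrix(streams, selected, corpus.doc_ids)


@pytest.fixture
def block_matrix():
    """Two row blocks on disjoint column sets: rank-1 CA geometry."""
    top = [[1, 1, 0, 0]] * 3
    bottom = [[0, 0, 1, 1]] * 3
    return np.array(top + bottom, dtype=float)
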