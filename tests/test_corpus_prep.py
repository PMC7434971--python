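import math

import numpy as np
import pytest

from textphase.corpus_prep import (LemmaDictionary, build_binary_matrix,
                                   lemmatize, rank_and_select_lemmas,
                                   read_corpus, read_lemma_dictionary,
                                   read_matrix_tsv, segment_corpus, tokenize)
from textphase.exceptions import DegenerateInputError
from textphase.synthetic_data import SimParams, generate_corpus, write_corpus


class TestSegmentation:
    def test_two_documents(self):
        corpus = segment_corpus([("d1", "A b, c."), ("d2", "d e")])
        assert len(corpus) == 2
        assert corpus.token_streams() == [["a", "b", "c"], ["d", "e"]]

    def test_punctuation_only_excluded(self, caplog):
        with caplog.at_level("WARNING", logger="textphase.corpus_prep"):
            corpus = segment_corpus([("d1", "a b"), ("d2", "?! ..."),
                                     ("d3", "c")])
        assert len(corpus) == 2
        assert "d2" in caplog.text
        assert [o for _, o, _ in corpus.docs] == [1, 2]

    def test_fewer_than_two_usable_raises(self):
        with pytest.raises(DegenerateInputError):
            segment_corpus([("d1", "hello"), ("d2", "...")])

    def test_tokenizer_drops_digits_and_underscores(self):
        assert tokenize("Ab1c x_y 42 ök") == ["ab", "c", "x", "y", "ök"]

    def test_synthetic_roundtrip_order(self, tmp_path):
        params = SimParams(n_docs=12, vocab_size=60, n_factors=3,
                           doc_length_range=(10, 20), shift_index=None,
                           seed=5)
        corpus, truth = generate_corpus(params)
        write_corpus(corpus, truth, params, tmp_path)
        loaded = read_corpus(tmp_path)
        assert loaded.doc_ids == corpus.doc_ids
        assert loaded.token_streams() == corpus.token_streams()


class TestLemmatize:
    def test_worked_example(self):
        corpus = segment_corpus([("d1", "goes went home"), ("d2", "went")])
        d = LemmaDictionary({"goes": "go", "went": "go"})
        assert lemmatize(corpus, d) == [["go", "go", "home"], ["go"]]

    def test_children_child(self):
        corpus = segment_corpus([("d1", "child children"), ("d2", "x")])
        d = LemmaDictionary({"children": "child"})
        assert lemmatize(corpus, d)[0] == ["child", "child"]

    def test_empty_dict_identity(self):
        corpus = segment_corpus([("d1", "Alpha Beta"), ("d2", "gamma")])
        assert lemmatize(corpus) == [["alpha", "beta"], ["gamma"]]

    def test_dictionary_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text("goes\tgo\nwent\tgo\n")
        d = read_lemma_dictionary(p)
        assert d["GOES"] == "go" and d["unknown"] == "unknown"


def streams_with_frequencies(freqs):
    """One lemma per distinct frequency; lemma names sort alphabetically
    in insertion order (aaa, aab, ...)."""
    import string
    names = []
    for i, _ in enumerate(freqs):
        a, rest = divmod(i, 26 * 26)
        b, c = divmod(rest, 26)
        names.append("a" + string.ascii_lowercase[a]
                     + string.ascii_lowercase[b] + string.ascii_lowercase[c])
    return [[n] * f for n, f in zip(names, freqs)], names


class TestRankAndSelect:
    def test_hundred_strictly_decreasing(self):
        streams, names = streams_with_frequencies(range(100, 0, -1))
        sel = rank_and_select_lemmas(streams)
        assert sel == names[5:15]  # drop ranks 1-5, keep 6-15

    @pytest.mark.parametrize("L,expected_drop,expected_keep", [
        (20, 1, 2), (100, 5, 10), (280, 14, 27), (1000, 50, 95)])
    def test_ceil_formulas(self, L, expected_drop, expected_keep):
        streams, names = streams_with_frequencies(range(L + 1, 1, -1))
        sel = rank_and_select_lemmas(streams)
        assert math.ceil(0.05 * L) == expected_drop
        assert len(sel) == expected_keep
        assert sel == names[expected_drop:expected_drop + expected_keep]

    def test_all_ties_alphabetical(self):
        streams, names = streams_with_frequencies([1] * 40)
        sel = rank_and_select_lemmas(streams)
        ordered = sorted(names)
        assert sel == ordered[2:6]  # drop ceil(2)=2, keep ceil(0.1*38)=4

    def test_no_exclusion(self):
        streams, names = streams_with_frequencies(range(30, 0, -1))
        sel = rank_and_select_lemmas(streams, exclude_top_frac=0.0)
        assert sel == names[:3]

    def test_too_few_lemmas_raises(self):
        streams, _ = streams_with_frequencies([3] * 10)
        with pytest.raises(DegenerateInputError, match="20"):
            rank_and_select_lemmas(streams)


class TestBinaryMatrix:
    def test_small_example(self):
        m = build_binary_matrix([["a", "b"], ["b", "c"]], ["a", "b", "c"])
        assert np.array_equal(m.values, [[1, 1, 0], [0, 1, 1]])

    def test_multiplicity_is_indicator(self):
        m = build_binary_matrix([["a"] * 5, ["b"]], ["a", "b"])
        assert m.values[0, 0] == 1

    def test_word_order_invariance(self):
        a = build_binary_matrix([["a", "b", "b"], ["c"]], ["a", "b", "c"])
        b = build_binary_matrix([["b", "a"], ["c", "c"]], ["a", "b", "c"])
        assert np.array_equal(a.values, b.values)

    def test_zero_column_removed(self, caplog):
        with caplog.at_level("WARNING", logger="textphase.corpus_prep"):
            m = build_binary_matrix([["a"], ["b"]], ["a", "b", "zzz"])
        assert m.lemmas == ("a", "b")

    def test_zero_row_flagged(self):
        m = build_binary_matrix([["a"], ["q"]], ["a"])
        assert m.zero_rows == (1,)

    def test_no_overlap_raises(self):
        with pytest.raises(DegenerateInputError):
            build_binary_matrix([["x"], ["y"]], ["a"])

    def test_row_sums_match_distinct_recount(self, small_corpus):
        corpus, _ = small_corpus
        streams = lemmatize(corpus)
        selected = rank_and_select_lemmas(streams)
        m = build_binary_matrix(streams, selected, corpus.doc_ids)
        sel = set(selected) & set(map(str, m.lemmas))
        for i, stream in enumerate(streams):
            assert m.values[i].sum() == len(set(stream) & set(m.lemmas))

    def test_tsv_roundtrip(self, tmp_path, small_matrix):
        p = tmp_path / "m.tsv"
        small_matrix.to_tsv(p)
        loaded = read_matrix_tsv(p)
        assert loaded.doc_ids == small_matrix.doc_ids
        assert loaded.lemmas == small_matrix.lemmas
        assert np.array_equal(loaded.values, small_matrix.values)

    def test_determinism(self, small_corpus):
        corpus, _ = small_corpus
        streams = lemmatize(corpus)
        a = rank_and_select_lemmas(streams)
        b = rank_and_select_lemmas(streams)
        assert a == b
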