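import numpy as np
import pytest

from textphase.affective_charge import euclidean_charge
from textphase.change_points import detect_change
from textphase.corpus_prep import (build_binary_matrix, lemmatize,
                                   rank_and_select_lemmas)
from textphase.exceptions import ConfigurationError
from textphase.factor_space import dream_vectors, fit_correspondence
from textphase.synthetic_data import (SimParams, build_vocabulary,
                                      generate_charge_series, generate_corpus,
                                      make_inflection_dictionary, write_corpus)


class TestSimParams:
    def test_vocab_too_small(self):
        with pytest.raises(ConfigurationError, match="3"):
            SimParams(vocab_size=25, n_factors=10)

    def test_bad_shift(self):
        with pytest.raises(ConfigurationError):
            SimParams(n_docs=10, shift_index=11)

    def test_bad_length_range(self):
        with pytest.raises(ConfigurationError):
            SimParams(doc_length_range=(50, 20))


class TestGenerateCorpus:
    def test_no_shift_constant_polarization(self):
        p = SimParams(n_docs=10, vocab_size=60, n_factors=3,
                      doc_length_range=(10, 20), shift_index=None,
                      polarization_pre=2.0, polarization_post=2.0, seed=1)
        _, truth = generate_corpus(p)
        assert truth.shift_index is None
        assert len(set(truth.per_doc_polarization)) == 1

    def test_same_seed_identical(self):
        p = SimParams(n_docs=8, vocab_size=60, n_factors=3,
                      doc_length_range=(10, 20), seed=9, shift_index=4)
        a, ta = generate_corpus(p)
        b, tb = generate_corpus(p)
        assert a.docs == b.docs
        assert ta == tb

    def test_different_seed_differs(self):
        base = dict(n_docs=8, vocab_size=60, n_factors=3,
                    doc_length_range=(10, 20), shift_index=4)
        a, _ = generate_corpus(SimParams(seed=1, **base))
        b, _ = generate_corpus(SimParams(seed=2, **base))
        assert a.docs != b.docs

    def test_truth_lengths(self, small_corpus, small_params):
        _, truth = small_corpus
        assert len(truth.per_doc_factor) == small_params.n_docs
        assert len(truth.per_doc_polarization) == small_params.n_docs

    def test_words_from_declared_vocabulary(self, small_corpus, small_params):
        corpus, _ = small_corpus
        vocab = set(build_vocabulary(small_params).all_words)
        for stream in corpus.token_streams():
            assert set(stream) <= vocab

    def test_mean_length_within_range(self, small_corpus, small_params):
        corpus, _ = small_corpus
        lo, hi = small_params.doc_length_range
        lengths = [len(s) for s in corpus.token_streams()]
        assert lo <= np.mean(lengths) <= hi
        assert all(lo <= l <= hi for l in lengths)

    def test_polarization_monotonicity(self):
        """Higher post-shift polarization -> higher mean post-shift max
        squared cosine (averaged over seeds)."""
        def post_shift_concentration(pol_post, seed):
            p = SimParams(n_docs=30, vocab_size=150, n_factors=3,
                          doc_length_range=(20, 60), shift_index=16,
                          polarization_pre=0.5, polarization_post=pol_post,
                          seed=seed)
            corpus, _ = generate_corpus(p)
            streams = lemmatize(corpus)
            m = build_binary_matrix(streams, rank_and_select_lemmas(streams),
                                    corpus.doc_ids)
            space = fit_correspondence(m, K=3)
            return dream_vectors(space).max(axis=1)[15:].mean()

        lo = np.mean([post_shift_concentration(1.0, s) for s in range(20)])
        hi = np.mean([post_shift_concentration(30.0, s) for s in range(20)])
        assert hi > lo

    def test_inflection_dictionary_restores_vocab(self):
        p = SimParams(n_docs=6, vocab_size=60, n_factors=3,
                      doc_length_range=(20, 30), shift_index=None, seed=2,
                      inflect=True)
        corpus, _ = generate_corpus(p)
        d = make_inflection_dictionary(p)
        vocab = set(build_vocabulary(p).all_words)
        for stream in lemmatize(corpus, d):
            assert set(stream) <= vocab

    def test_write_corpus_outputs(self, tmp_path):
        p = SimParams(n_docs=5, vocab_size=60, n_factors=3,
                      doc_length_range=(5, 10), shift_index=3, seed=0)
        corpus, truth = generate_corpus(p)
        out = write_corpus(corpus, truth, p, tmp_path / "c")
        assert (out / "manifest.tsv").exists()
        assert (out / "params.json").exists()
        assert sorted(f.name for f in out.glob("*.txt")) == \
            [f"doc_{i:04d}.txt" for i in range(1, 6)]


class TestGenerateChargeSeries:
    def test_determinism(self):
        a = generate_charge_series(50, seed=3)
        b = generate_charge_series(50, seed=3)
        assert np.array_equal(a, b)

    def test_zero_noise_deterministic_path(self):
        y = generate_charge_series(20, noise_sd=0.0, seed=1)
        assert np.var(np.diff(y)) == 0.0

    def test_var_ratio_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_charge_series(50, var_ratio=0.5, var_shift_index=10)

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_charge_series(50, ar=1.0)

    def test_null_case_low_detection_rate(self):
        # random-walk innovations are white noise, so the calibrated
        # threshold should rarely fire on the differenced path
        hits = sum(
            detect_change(np.diff(
                generate_charge_series(95, ar=0.0, ma=0.0, seed=s))).index
            is not None for s in range(50))
        assert hits <= 5  # >= 90% of 50 seeds without detection

    def test_variance_shift_recovered(self):
        hits = 0
        for s in range(50):
            y = generate_charge_series(95, ar=0.0, ma=0.0, noise_sd=1.0,
                                       var_shift_index=58, var_ratio=9,
                                       seed=s)
            idx = detect_change(np.diff(y)).index
            # diff index k corresponds to level index k+1
            hits += idx is not None and abs((idx + 1) - 58) <= 4
        assert hits >= 40  # >= 80% of 50 seeds

    def test_mean_trend_unchanged_by_shift(self):
        # multiplicative shift acts on innovations, not levels: with zero
        # noise both paths coincide regardless of var_ratio
        a = generate_charge_series(30, noise_sd=0.0, seed=1)
        b = generate_charge_series(30, noise_sd=0.0, var_shift_index=15,
                                   var_ratio=9, seed=1)
        assert np.allclose(a, b)
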