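"""Synthetic corpora and charge series with a known regime shift.

The corpus generator emits ordered documents drawn from a factor-topic
model: the vocabulary is partitioned into a small shared function-word
pool (very high frequency, meant to be removed by the 5% exclusion), one
disjoint core vocabulary per factor, and a large uniform background pool.
Each document owns one factor; every content token comes from the
document's own core with a probability controlled by the document's
polarization (odds ``pol : 1`` of own-core vs another factor's core).
Documents at and after ``shift_index`` use ``polarization_post``, so the
post-shift rows of the indicator matrix concentrate on single factor
blocks — the squared-cosine signal the downstream analysis detects.

All generation is driven by ``numpy.random.default_rng(seed)`` only, so
identical parameters give byte-identical output.
"""
from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_prep import DocumentCorpus, LemmaDictionary
from .exceptions import ConfigurationError

__all__ = [
    "SimParams",
    "SimTruth",
    "generate_corpus",
    "generate_charge_series",
    "make_inflection_dictionary",
    "write_corpus",
    "write_series_tsv",
]

_SUFFIXES = ("s", "ed", "ing")

#: token-level mixture weights (before polarization splits the core draw)
_P_FUNC = 0.25
_P_BACKGROUND = 0.30


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic factor-topic corpus."""

    n_docs: int = 95
    vocab_size: int = 600
    n_factors: int = 10
    doc_length_range: tuple[int, int] = (30, 400)
    polarization_pre: float = 0.5
    polarization_post: float = 49.0
    shift_index: int | None = 58
    seed: int = 0
    inflect: bool = False

    def __post_init__(self):
        if self.n_docs < 1 or self.vocab_size < 1 or self.n_factors < 1:
            raise ConfigurationError("counts must be positive")
        lo, hi = self.doc_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("doc_length_range must satisfy 0 < min <= max")
        if self.polarization_pre < 0 or self.polarization_post < 0:
            raise ConfigurationError("polarization must be >= 0")
        if self.shift_index is not None and not (
                1 <= self.shift_index <= self.n_docs):
            raise ConfigurationError("shift_index must lie in [1, n_docs]")
        if self.vocab_size < 3 * self.n_factors:
            raise ConfigurationError(
                f"vocab_size={self.vocab_size} too small: topics need >= 3 "
                f"core words each ({3 * self.n_factors} total)")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a generated corpus."""

    shift_index: int | None
    per_doc_factor: tuple[int, ...]
    per_doc_polarization: tuple[float, ...]


def _codeword(prefix: str, idx: int) -> str:
    letters = []
    for _ in range(3):
        idx, rem = divmod(idx, 26)
        letters.append(string.ascii_lowercase[rem])
    return prefix + "".join(reversed(letters))


@dataclass(frozen=True)
class Vocabulary:
    function_words: tuple[str, ...]
    cores: tuple[tuple[str, ...], ...]  # one tuple per factor
    background: tuple[str, ...]

    @property
    def all_words(self) -> tuple[str, ...]:
        return (self.function_words
                + tuple(w for core in self.cores for w in core)
                + self.background)


def build_vocabulary(params: SimParams) -> Vocabulary:
    """Partition the vocabulary into function / core / background pools."""
    v, f = params.vocab_size, params.n_factors
    n_func = min(max(2, round(0.02 * v)), v - 3 * f)
    n_func = max(n_func, 0)
    core_size = max(3, (v - n_func) // (3 * f))
    if n_func + core_size * f > v:
        core_size = (v - n_func) // f
    func = tuple(_codeword("f", i) for i in range(n_func))
    cores = tuple(
        tuple(_codeword("c", k * core_size + i) for i in range(core_size))
        for k in range(f))
    n_bg = v - n_func - core_size * f
    background = tuple(_codeword("b", i) for i in range(n_bg))
    return Vocabulary(func, cores, background)


def _own_core_prob(pol: float) -> float:
    # polarization expressed as odds of own-core vs any-other-core
    return pol / (1.0 + pol)


def generate_corpus(params: SimParams) -> tuple[DocumentCorpus, SimTruth]:
    """Generate an ordered corpus with a latent factor structure.

    Returns the corpus plus the ground truth (factor label and
    polarization per document, and the injected shift index).
    """
    rng = np.random.default_rng(params.seed)
    vocab = build_vocabulary(params)
    n_func = len(vocab.function_words)
    # Zipf-like weights so function words dominate the frequency ranking
    func_w = 1.0 / np.arange(1, n_func + 1) if n_func else np.empty(0)
    func_w = func_w / func_w.sum() if n_func else func_w
    p_bg = _P_BACKGROUND if vocab.background else 0.0

    lo, hi = params.doc_length_range
    factors = rng.integers(0, params.n_factors, size=params.n_docs)
    lengths = rng.integers(lo, hi + 1, size=params.n_docs)

    docs = []
    polarizations = []
    for i in range(params.n_docs):
        pre = params.shift_index is None or (i + 1) < params.shift_index
        pol = params.polarization_pre if pre else params.polarization_post
        polarizations.append(pol)
        p_own = _own_core_prob(pol)
        own = factors[i]
        words = []
        u = rng.random((lengths[i], 3))
        for u_kind, u_bg, u_own in u:
            if n_func and u_kind < _P_FUNC:
                words.append(vocab.function_words[
                    rng.choice(n_func, p=func_w)])
            elif u_bg < p_bg:
                words.append(vocab.background[
                    rng.integers(len(vocab.background))])
            else:
                if u_own < p_own:
                    core = vocab.cores[own]
                else:
                    other = rng.integers(params.n_factors)
                    core = vocab.cores[other]
                words.append(core[rng.integers(len(core))])
        if params.inflect:
            infl = rng.random(len(words))
            words = [w + _SUFFIXES[rng.integers(len(_SUFFIXES))]
                     if (infl[j] < 0.3 and not w.startswith("f")) else w
                     for j, w in enumerate(words)]
        docs.append((f"doc_{i + 1:04d}", i + 1, " ".join(words)))

    corpus = DocumentCorpus(tuple(docs), language_tag="zxx")
    truth = SimTruth(params.shift_index, tuple(int(f) for f in factors),
                     tuple(polarizations))
    return corpus, truth


def make_inflection_dictionary(params: SimParams) -> LemmaDictionary:
    """Lemma dictionary undoing the optional suffix inflection."""
    vocab = build_vocabulary(params)
    mapping = {}
    for w in vocab.all_words:
        for suf in _SUFFIXES:
            mapping[w + suf] = w
    return LemmaDictionary(mapping)


def generate_charge_series(
    n: int,
    ar: float = -0.24,
    ma: float = 0.8,
    noise_sd: float = 1.0,
    var_shift_index: int | None = None,
    var_ratio: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Integrated ARMA(1,1) path with an optional innovation-variance shift.

    Innovations from position ``var_shift_index`` (1-based) onward have
    their standard deviation multiplied by ``sqrt(var_ratio)``; the shift
    acts on the innovations (not the levels), so only the variance regime
    changes, never the mean trend.
    """
    if n < 10:
        raise ConfigurationError("n must be >= 10")
    if abs(ar) >= 1:
        raise ConfigurationError("|ar| must be < 1")
    if var_ratio < 1:
        raise ConfigurationError("var_ratio must be >= 1 (shift must not "
                                 "decrease variance)")
    if var_shift_index is not None and not (1 <= var_shift_index <= n):
        raise ConfigurationError("var_shift_index must lie in [1, n]")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n) * noise_sd
    if var_shift_index is not None:
        eps[var_shift_index - 1:] *= np.sqrt(var_ratio)
    z = np.empty(n)
    z[0] = eps[0]
    for t in range(1, n):
        z[t] = ar * z[t - 1] + eps[t] + ma * eps[t - 1]
    return np.cumsum(z)


# ---------------------------------------------------------------------------
# file output

def write_corpus(corpus: DocumentCorpus, truth: SimTruth, params: SimParams,
                 outdir) -> Path:
    """Write one UTF-8 .txt per document, a TSV manifest with the truth
    columns, and the parameters as JSON.  Returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (doc_id, order, text), fac, pol in zip(
            corpus.docs, truth.per_doc_factor, truth.per_doc_polarization):
        (out / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        rows.append({"id": doc_id, "order": order, "factor": fac,
                     "polarization": pol})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    payload = asdict(params)
    payload["shift_index_truth"] = truth.shift_index
    (out / "params.json").write_text(json.dumps(payload, indent=2))
    return out


def write_series_tsv(series, path) -> None:
    """Two-column TSV (1-based index, value)."""
    arr = np.asarray(series, dtype=float).ravel()
    pd.DataFrame({"index": np.arange(1, len(arr) + 1), "value": arr}) \
        .to_csv(path, sep="\t", index=False)
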