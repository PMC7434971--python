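"""From raw ordered documents to the binary document x lemma matrix.

Steps: segment into one elementary context unit (ECU) per document,
tokenise (lowercase, split on non-letter characters), lemmatise via a
surface-form -> lemma dictionary, rank lemmas by corpus frequency, drop
the top ``exclude_top_frac`` (function-word proxy), select the most
frequent ``select_frac`` of the remainder, and build a 0/1 indicator
matrix (1 iff the lemma occurs at least once in the ECU).

Fraction counts use ``ceil``; frequency ties are broken alphabetically.
"""
from __future__ import annotations

import logging
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError

__all__ = [
    "DocumentCorpus",
    "LemmaDictionary",
    "LemmaMatrix",
    "tokenize",
    "segment_corpus",
    "lemmatize",
    "rank_and_select_lemmas",
    "build_binary_matrix",
    "read_corpus",
    "read_lemma_dictionary",
    "read_matrix_tsv",
]

log = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

MIN_DISTINCT_LEMMAS = 20


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-letter characters; drops empty tokens."""
    return _TOKEN_RE.findall(unicodedata.normalize("NFC", text).lower())


@dataclass(frozen=True)
class DocumentCorpus:
    """Ordered documents, one ECU each."""

    docs: tuple[tuple[str, int, str], ...]  # (doc_id, order_index, text)
    language_tag: str = "und"

    def __post_init__(self):
        orders = [o for _, o, _ in self.docs]
        if orders != list(range(1, len(orders) + 1)):
            raise ValueError("order_index values must be 1..N without gaps")
        for doc_id, _, text in self.docs:
            if not text.strip():
                raise ValueError(f"document {doc_id!r} is empty")

    def __len__(self) -> int:
        return len(self.docs)

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _, _ in self.docs]

    def token_streams(self) -> list[list[str]]:
        return [tokenize(text) for _, _, text in self.docs]


class LemmaDictionary:
    """Total surface-form -> lemma lookup; unknown forms map to themselves."""

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map = {k.lower(): v.lower() for k, v in (mapping or {}).items()}

    def __len__(self) -> int:
        return len(self._map)

    def __getitem__(self, form: str) -> str:
        return self._map.get(form.lower(), form.lower())

    def get(self, form: str) -> str:
        return self[form]


@dataclass(frozen=True)
class LemmaMatrix:
    """Binary documents x lemmas indicator matrix."""

    doc_ids: tuple[str, ...]
    lemmas: tuple[str, ...]
    values: np.ndarray  # 0/1, shape (n_docs, n_lemmas)
    zero_rows: tuple[int, ...] = ()  # flagged all-zero rows (0-based)

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.doc_ids), len(self.lemmas)):
            raise ValueError("shape mismatch between labels and values")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.doc_ids),
                            columns=list(self.lemmas))

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "doc_id"
        df.to_csv(path, sep="\t")


def segment_corpus(raw_inputs, language_tag: str = "und") -> DocumentCorpus:
    """Build an ordered corpus of ECUs from (doc_id, text) pairs.

    Documents that contain no tokens (e.g. punctuation only) are excluded
    with a logged warning; at least 2 usable documents must remain.
    """
    docs = []
    order = 0
    for doc_id, text in raw_inputs:
        if not tokenize(text):
            log.warning("excluding empty document %r", doc_id)
            continue
        order += 1
        docs.append((str(doc_id), order, text))
    if len(docs) < 2:
        raise DegenerateInputError(
            f"need at least 2 usable documents, got {len(docs)}")
    return DocumentCorpus(tuple(docs), language_tag)


def lemmatize(corpus: DocumentCorpus,
              dictionary: LemmaDictionary | None = None) -> list[list[str]]:
    """Replace each token of each ECU by its lemma (total mapping)."""
    d = dictionary or LemmaDictionary()
    return [[d[tok] for tok in stream] for stream in corpus.token_streams()]


def rank_and_select_lemmas(
    corpus_lemmas: list[list[str]],
    exclude_top_frac: float = 0.05,
    select_frac: float = 0.10,
) -> list[str]:
    """Frequency-rank lemmas, drop the top slice, select from the rest.

    With ``L`` distinct lemmas, the ``ceil(exclude_top_frac * L)`` most
    frequent are dropped; of the remaining ``L'``, the
    ``ceil(select_frac * L')`` most frequent are selected.  Ranking is by
    descending corpus frequency, ties alphabetical.  Returns the selected
    lemmas in rank order.
    """
    if not 0 <= exclude_top_frac < 1 or not 0 < select_frac <= 1:
        raise ValueError("fractions must satisfy 0<=exclude<1, 0<select<=1")
    freq = Counter(lem for stream in corpus_lemmas for lem in stream)
    n_distinct = len(freq)
    if n_distinct < MIN_DISTINCT_LEMMAS:
        raise DegenerateInputError(
            f"need at least {MIN_DISTINCT_LEMMAS} distinct lemmas, "
            f"got {n_distinct}")
    ranked = sorted(freq, key=lambda w: (-freq[w], w))
    n_drop = math.ceil(exclude_top_frac * n_distinct)
    remainder = ranked[n_drop:]
    n_keep = math.ceil(select_frac * len(remainder))
    selected = remainder[:n_keep]
    log.info("lemma selection: %d distinct, dropped top %d, kept %d of %d",
             n_distinct, n_drop, n_keep, len(remainder))
    return selected


def build_binary_matrix(
    corpus_lemmas: list[list[str]],
    selected: list[str],
    doc_ids: list[str] | None = None,
) -> LemmaMatrix:
    """Indicator matrix: 1 iff the lemma occurs at least once in the ECU.

    All-zero rows are retained but flagged; all-zero columns are removed
    with a warning.  Raises when every row is all-zero (selection and
    corpus do not overlap).
    """
    if not selected:
        raise ValueError("selected lemma list is empty")
    if doc_ids is None:
        doc_ids = [f"doc_{i + 1:04d}" for i in range(len(corpus_lemmas))]
    col_of = {lem: j for j, lem in enumerate(selected)}
    m = np.zeros((len(corpus_lemmas), len(selected)), dtype=np.int8)
    for i, stream in enumerate(corpus_lemmas):
        for lem in stream:
            j = col_of.get(lem)
            if j is not None:
                m[i, j] = 1
    zero_rows = tuple(int(i) for i in np.flatnonzero(m.sum(axis=1) == 0))
    if len(zero_rows) == len(corpus_lemmas):
        raise DegenerateInputError(
            "no overlap between selected lemmas and corpus (all rows zero)")
    if zero_rows:
        log.warning("%d document(s) contain no selected lemma: rows %s",
                    len(zero_rows), zero_rows)
    col_keep = m.sum(axis=0) > 0
    if not col_keep.all():
        dropped = [selected[j] for j in np.flatnonzero(~col_keep)]
        log.warning("removing %d all-zero column(s): %s", len(dropped), dropped)
    lemmas = tuple(lem for lem, k in zip(selected, col_keep) if k)
    return LemmaMatrix(tuple(doc_ids), lemmas, m[:, col_keep], zero_rows)


# ---------------------------------------------------------------------------
# file I/O

def read_corpus(path) -> DocumentCorpus:
    """Read a corpus from a directory of .txt files (with optional TSV
    manifest fixing the order) or from a single TSV with id/text columns."""
    p = Path(path)
    if p.is_dir():
        manifest = p / "manifest.tsv"
        if manifest.exists():
            mf = pd.read_csv(manifest, sep="\t")
            mf = mf.sort_values("order") if "order" in mf else mf
            pairs = [(row["id"], (p / f"{row['id']}.txt").read_text("utf-8"))
                     for _, row in mf.iterrows()]
        else:
            pairs = [(f.stem, f.read_text("utf-8"))
                     for f in sorted(p.glob("*.txt"))]
    else:
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
        id_col, text_col = df.columns[:2]
        pairs = list(zip(df[id_col], df[text_col]))
    return segment_corpus(pairs)


def read_lemma_dictionary(path) -> LemmaDictionary:
    """Two-column TSV: surface form, lemma.  No header required."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["form", "lemma"]).dropna()
    return LemmaDictionary(dict(zip(df["form"], df["lemma"])))


def read_matrix_tsv(path) -> LemmaMatrix:
    """Read a LemmaMatrix written by :meth:`LemmaMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    zero_rows = tuple(int(i) for i in np.flatnonzero(vals.sum(axis=1) == 0))
    return LemmaMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                       vals.astype(np.int8), zero_rows)
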