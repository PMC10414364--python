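"""Bag-of-words vectorization with collocation-detected n-grams (n = 1–5).

Text normalization is deliberately light: the PII mask string is removed and
the text lowercased, but punctuation, numerals and stop words are retained —
they carry clinical information and appear inside abbreviations.  Tokens are
whitespace-delimited, so punctuation-bearing tokens ("s/p", "120/80", "dr.")
are terms in their own right.

Multiword terms are admitted by an iterative collocation (phrase) score on
adjacent tokens,

    score(a, b) = (count(ab) − δ) · N / (count(a) · count(b)),

with discount δ guarding against rare accidental pairs; each pass may join an
admitted phrase with a neighbour, growing phrases up to ``max_n`` tokens.
Counting is greedy left-to-right longest-match: tokens absorbed into an
admitted phrase occurrence are, by default, not double-counted as their
component unigrams (a flag restores component counting).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import scipy.io
import scipy.sparse as sp

from .exceptions import ConfigError


def normalize_text(text: str, pii_mask: str = "") -> str:
    """Remove every occurrence of the PII mask string, then lowercase."""
    if pii_mask:
        text = text.replace(pii_mask, "")
    return text.lower()


@dataclass
class Vocabulary:
    """Ordered term list (lexicographic) with a dense term → column map."""

    terms: List[str]
    index: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ConfigError("vocabulary terms must be unique")
        self.index = {t: j for j, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    @property
    def max_tokens(self) -> int:
        return max((len(t.split()) for t in self.terms), default=1)


def _grow_phrases(token_docs: List[List[str]], max_n: int, min_count: int,
                  threshold: float, discount: float) -> set:
    """Iteratively admit adjacent-unit merges whose collocation score passes."""
    phrases: set = set()
    streams = [list(doc) for doc in token_docs]
    for _ in range(max_n - 1):
        unit_counts: Counter = Counter()
        pair_counts: Counter = Counter()
        for doc in streams:
            unit_counts.update(doc)
            pair_counts.update(zip(doc, doc[1:]))
        total_units = sum(unit_counts.values())
        admitted = set()
        for (a, b), c_ab in pair_counts.items():
            n_tok = len(a.split()) + len(b.split())
            if n_tok > max_n or c_ab < min_count:
                continue
            score = (c_ab - discount) * total_units / (unit_counts[a] * unit_counts[b])
            if score > threshold:
                admitted.add((a, b))
        if not admitted:
            break
        phrases.update(f"{a} {b}" for a, b in admitted)
        new_streams = []
        for doc in streams:
            out: List[str] = []
            i = 0
            while i < len(doc):
                if i + 1 < len(doc) and (doc[i], doc[i + 1]) in admitted:
                    out.append(f"{doc[i]} {doc[i + 1]}")
                    i += 2
                else:
                    out.append(doc[i])
                    i += 1
            new_streams.append(out)
        streams = new_streams
    return phrases


def build_vocabulary(documents: Sequence[str], max_n: int = 5,
                     collocation_min_count: int = 5,
                     collocation_threshold: float = 10.0,
                     discount: float = 5.0) -> Vocabulary:
    """All unigrams plus collocation-admitted phrases, sorted lexicographically."""
    if not 1 <= max_n <= 5:
        raise ConfigError(f"max_n must be in 1..5, got {max_n}")
    token_docs = [doc.split() for doc in documents]
    unigrams = set()
    for doc in token_docs:
        unigrams.update(doc)
    if not unigrams:
        raise ConfigError("empty corpus: no tokens to build a vocabulary from")
    phrases: set = set()
    if max_n > 1:
        phrases = _grow_phrases(token_docs, max_n, collocation_min_count,
                                collocation_threshold, discount)
    return Vocabulary(sorted(unigrams | phrases))


@dataclass
class TermMatrix:
    """Sparse nonnegative integer document × term count matrix."""

    doc_ids: List[str]
    vocabulary: Vocabulary
    counts: sp.csr_matrix

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def term_counts(self) -> np.ndarray:
        """Raw corpus occurrence count per term (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def doc_frequency(self) -> np.ndarray:
        """Number of documents containing each term at least once."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def restrict(self, terms: Sequence[str]) -> "TermMatrix":
        """Columns restricted to ``terms`` (re-sorted lexicographically);
        equals re-vectorizing with that sub-vocabulary when the sub-vocabulary
        is closed under the longest-match rule."""
        missing = [t for t in terms if t not in self.vocabulary]
        if missing:
            raise ConfigError(f"terms not in vocabulary: {missing[:5]}...")
        sub = Vocabulary(sorted(set(terms)))
        cols = [self.vocabulary.index[t] for t in sub.terms]
        return TermMatrix(list(self.doc_ids), sub,
                          self.counts[:, cols].tocsr())

    def rows(self, keep: Sequence[int]) -> "TermMatrix":
        return TermMatrix([self.doc_ids[i] for i in keep], self.vocabulary,
                          self.counts[list(keep), :].tocsr())

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.mtx (Matrix Market), <prefix>.vocab.txt, <prefix>.docs.txt."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), self.counts.tocoo())
        prefix.with_suffix(".vocab.txt").write_text(
            "\n".join(self.vocabulary.terms) + "\n")
        prefix.with_suffix(".docs.txt").write_text("\n".join(self.doc_ids) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "TermMatrix":
        prefix = Path(prefix)
        counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
        terms = prefix.with_suffix(".vocab.txt").read_text().splitlines()
        doc_ids = prefix.with_suffix(".docs.txt").read_text().splitlines()
        return cls(doc_ids, Vocabulary(terms), counts.astype(np.int64))


def vectorize_documents(documents: Sequence[str], vocabulary: Vocabulary,
                        doc_ids: Sequence[str] | None = None,
                        count_unigrams_in_phrases: bool = False) -> TermMatrix:
    """Count term occurrences per document (greedy longest-match).

    Out-of-vocabulary tokens contribute nothing.  When a multiword term
    matches, its component unigrams are not counted inside that occurrence
    unless ``count_unigrams_in_phrases`` is set.
    """
    if len(vocabulary) == 0:
        raise ConfigError("vocabulary is empty")
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(documents))]
    max_len = vocabulary.max_tokens
    rows: List[int] = []
    cols: List[int] = []
    vals: List[int] = []
    for i, doc in enumerate(documents):
        tokens = doc.split()
        counts: Counter = Counter()
        pos = 0
        while pos < len(tokens):
            matched = False
            for n in range(min(max_len, len(tokens) - pos), 0, -1):
                cand = " ".join(tokens[pos:pos + n])
                if cand in vocabulary.index:
                    counts[vocabulary.index[cand]] += 1
                    if n > 1 and count_unigrams_in_phrases:
                        for tok in tokens[pos:pos + n]:
                            j = vocabulary.index.get(tok)
                            if j is not None:
                                counts[j] += 1
                    pos += n
                    matched = True
                    break
            if not matched:
                pos += 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    counts_mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(documents), len(vocabulary)),
        dtype=np.int64)
    return TermMatrix(list(doc_ids), vocabulary, counts_mat)
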