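"""Latent Dirichlet allocation over the trimmed target-group matrix.

The model is fit with batch variational inference (deterministic under a fixed
seed) and symmetric Dirichlet priors α = η = 1/K by default.  Two views of the
fit are exposed:

* ``term_topic`` — the K × V variational topic-term matrix in *pseudo-count*
  scale (η plus expected term assignments).  Top-term scores on this scale are
  large and integer-like for dominant terms; a normalized probability view is
  available via :meth:`TopicModelResult.term_topic_probabilities`.
* ``doc_topic`` — the D × K document-topic probability matrix; every row sums
  to 1.  A document with zero in-vocabulary terms carries no evidence, so its
  variational posterior equals the symmetric prior and it scores exactly 1/K
  for every topic (0.022 at K = 45).

Because rows are normalized, at most floor(1/t) topics can reach a score ≥ t
in one document (33 topics at the significance threshold t = 0.03).

K must be chosen a priori; :func:`tune_k` fits a list of candidate K values
and reports simple coherence diagnostics to support the (ultimately human)
choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from .exceptions import ConfigError
from .vectorize import TermMatrix

#: document-topic score bands used in the topic summaries
SCORE_BANDS: Tuple[float, float, float, float] = (0.5, 0.2, 0.1, 0.03)
#: a topic counts toward a document's topic multiplicity above this score
SIG_THRESHOLD: float = 0.03


@dataclass
class TopicModelResult:
    K: int
    term_topic: np.ndarray        # K × V pseudo-count term scores
    doc_topic: np.ndarray         # D × K probabilities, rows sum to 1
    terms: List[str]
    doc_ids: List[str]
    seed: int
    alpha: float
    eta: float
    n_iter: int

    def top_terms(self, topic: int, n: int = 20) -> List[Tuple[str, float]]:
        """Top-n terms of one topic by descending term score (ties by term)."""
        scores = self.term_topic[topic]
        order = sorted(range(len(self.terms)),
                       key=lambda j: (-scores[j], self.terms[j]))
        return [(self.terms[j], float(scores[j])) for j in order[:n]]

    def term_topic_probabilities(self) -> np.ndarray:
        """Row-normalized term-topic matrix (each topic a distribution)."""
        return self.term_topic / self.term_topic.sum(axis=1, keepdims=True)

    def topics_per_document(self, threshold: float = SIG_THRESHOLD) -> np.ndarray:
        return (self.doc_topic >= threshold).sum(axis=1)


@dataclass
class TopicSummary:
    """Per-topic report: top term score, top terms, top document score and
    document counts per score band (bands are disjoint)."""

    table: pd.DataFrame
    bands: Tuple[float, ...] = SCORE_BANDS


def fit_lda(matrix: TermMatrix, K: int, seed: int = 0,
            alpha: Optional[float] = None, eta: Optional[float] = None,
            max_iter: int = 100) -> TopicModelResult:
    """Fit a K-topic LDA model (batch variational, symmetric priors)."""
    if K < 2:
        raise ConfigError(f"K must be >= 2, got {K}")
    D, V = matrix.shape
    if D == 0 or V == 0:
        raise ConfigError("cannot fit LDA on an empty matrix")
    if D < K:
        raise ConfigError(f"need at least K={K} documents, got {D}")
    alpha = 1.0 / K if alpha is None else alpha
    eta = 1.0 / K if eta is None else eta
    lda = LatentDirichletAllocation(
        n_components=K,
        doc_topic_prior=alpha,
        topic_word_prior=eta,
        learning_method="batch",
        max_iter=max_iter,
        mean_change_tol=1e-4,
        random_state=seed,
    )
    doc_topic = lda.fit_transform(matrix.counts)
    return TopicModelResult(
        K=K,
        term_topic=lda.components_,
        doc_topic=doc_topic,
        terms=list(matrix.vocabulary.terms),
        doc_ids=list(matrix.doc_ids),
        seed=seed,
        alpha=alpha,
        eta=eta,
        n_iter=int(lda.n_iter_),
    )


@dataclass
class KTuningDiagnostics:
    K: int
    n_coherent: int               # topics whose top document score >= 0.5
    n_low_score: int              # topics whose top document score < 0.1
    mean_topics_per_doc: float    # at the 0.03 significance threshold


def tune_k(matrix: TermMatrix, K_list: Sequence[int], seed: int = 0,
           coherent_threshold: float = 0.5, low_threshold: float = 0.1,
           sig_threshold: float = SIG_THRESHOLD, max_iter: int = 100,
           ) -> List[Tuple[int, TopicModelResult, KTuningDiagnostics]]:
    """Fit one model per candidate K and report coherence diagnostics."""
    if not K_list:
        raise ConfigError("K_list must be nonempty")
    out = []
    for K in K_list:
        result = fit_lda(matrix, K, seed=seed, max_iter=max_iter)
        top_doc = result.doc_topic.max(axis=0)    # per-topic best document
        diag = KTuningDiagnostics(
            K=K,
            n_coherent=int((top_doc >= coherent_threshold).sum()),
            n_low_score=int((top_doc < low_threshold).sum()),
            mean_topics_per_doc=float(
                result.topics_per_document(sig_threshold).mean()),
        )
        out.append((K, result, diag))
    return out


def summarize_topics(result: TopicModelResult, top_n: int = 20,
                     bands: Sequence[float] = SCORE_BANDS) -> TopicSummary:
    """Per-topic top terms and banded document counts, sorted by top document
    score descending (ties by topic index)."""
    if top_n > len(result.terms):
        raise ConfigError(f"top_n={top_n} exceeds vocabulary size "
                          f"{len(result.terms)}")
    bands = tuple(sorted(bands, reverse=True))
    edges = list(bands) + [None]
    rows = []
    for k in range(result.K):
        scores = result.doc_topic[:, k]
        row: Dict[str, object] = {
            "topic": k,
            "top_term_score": float(result.term_topic[k].max()),
            "top_terms": ", ".join(t for t, _ in result.top_terms(k, top_n)),
            "top_doc_score": float(scores.max()) if len(scores) else 0.0,
        }
        row[f"n_ge_{bands[0]:g}"] = int((scores >= bands[0]).sum())
        for hi, lo in zip(bands[:-1], bands[1:]):
            row[f"n_{lo:g}_{hi:g}"] = int(((scores >= lo) & (scores < hi)).sum())
        row[f"n_ge_{bands[-1]:g}_total"] = int((scores >= bands[-1]).sum())
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["top_doc_score", "topic"], ascending=[False, True]).reset_index(drop=True)
    return TopicSummary(table=table, bands=bands)
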