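"""Selection of documents for human review.

Three selection routes feed the review queue: the top-k documents per topic,
the documents whose score reaches the significance threshold in the most
topics (clinically complex admissions), and an independent uniform random
sample (which is *not* forced disjoint from the other two routes).

Also builds the review-planning tables: the histogram of per-document maximum
topic scores and the cross-table of topic multiplicity × maximum-score band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .topic_model import SIG_THRESHOLD


@dataclass
class ReviewSet:
    per_topic: Dict[int, List[Tuple[str, float]]]   # topic -> [(doc_id, score)]
    multi_topic: List[Tuple[str, int]]              # (doc_id, n significant topics)
    random_sample: List[str]
    params: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "per_topic": {str(k): v for k, v in self.per_topic.items()},
            "multi_topic": self.multi_topic,
            "random_sample": self.random_sample,
            "params": self.params,
        }, indent=2, sort_keys=True)


def select_review_set(doc_topic: np.ndarray,
                      doc_ids: Optional[Sequence[str]] = None,
                      top_k: int = 3, sig_threshold: float = SIG_THRESHOLD,
                      n_multi: int = 7, n_random: int = 24, seed: int = 0,
                      exclude_ids: Optional[Sequence[str]] = None) -> ReviewSet:
    """Pick review documents: top-k per topic, n_multi most-multi-topic,
    n_random uniform without replacement.

    Topic-score ties break by ascending document id.  ``exclude_ids`` removes
    documents from the random-sample pool only (stand-in for the manual
    clinical screening of the random sample).
    """
    if top_k < 1:
        raise ConfigError("top_k must be >= 1")
    if not 0.0 < sig_threshold < 1.0:
        raise ConfigError("sig_threshold must be in (0, 1)")
    D, K = doc_topic.shape
    if doc_ids is None:
        doc_ids = [str(i) for i in range(D)]
    doc_ids = list(doc_ids)
    if len(doc_ids) != D:
        raise ConfigError("doc_ids length must match doc_topic rows")

    per_topic: Dict[int, List[Tuple[str, float]]] = {}
    for k in range(K):
        order = sorted(range(D), key=lambda i: (-doc_topic[i, k], doc_ids[i]))
        per_topic[k] = [(doc_ids[i], float(doc_topic[i, k]))
                        for i in order[:top_k]]

    n_topics = (doc_topic >= sig_threshold).sum(axis=1)
    multi_order = sorted(range(D), key=lambda i: (-n_topics[i], doc_ids[i]))
    multi = [(doc_ids[i], int(n_topics[i])) for i in multi_order[:n_multi]]

    pool = doc_ids
    if exclude_ids:
        excluded = set(exclude_ids)
        pool = [d for d in doc_ids if d not in excluded]
    if n_random > len(pool):
        raise ConfigError(f"n_random={n_random} exceeds available documents "
                          f"({len(pool)})")
    rng = np.random.default_rng(seed)
    sample = [pool[i] for i in rng.choice(len(pool), size=n_random,
                                          replace=False)]

    return ReviewSet(
        per_topic=per_topic,
        multi_topic=multi,
        random_sample=sample,
        params={"top_k": top_k, "sig_threshold": sig_threshold,
                "n_multi": n_multi, "n_random": n_random, "seed": seed},
    )


def max_topic_table(doc_topic: np.ndarray, sig_threshold: float = SIG_THRESHOLD,
                    bands: Sequence[float] = (0.5, 0.2, 0.1)) -> pd.DataFrame:
    """Cross-table: rows = number of topics with score ≥ threshold, columns =
    bands of the per-document maximum score.

    A final catch-all column covers maxima below the lowest band so the table
    totals the corpus size.  Row indices are bounded by floor(1/threshold).
    """
    if doc_topic.size == 0:
        raise ConfigError("doc_topic is empty")
    bands = sorted(bands, reverse=True)
    n_topics = (doc_topic >= sig_threshold).sum(axis=1)
    max_scores = doc_topic.max(axis=1)

    col_names = [f"score>={bands[0]:g}"]
    col_names += [f"{lo:g}<=score<{hi:g}" for hi, lo in zip(bands[:-1], bands[1:])]
    col_names += [f"score<{bands[-1]:g}"]

    def band_of(s: float) -> int:
        for b, edge in enumerate(bands):
            if s >= edge:
                return b
        return len(bands)

    max_row = int(n_topics.max())
    table = np.zeros((max_row + 1, len(col_names)), dtype=int)
    for nt, ms in zip(n_topics, max_scores):
        table[int(nt), band_of(float(ms))] += 1
    df = pd.DataFrame(table, columns=col_names)
    df.index.name = f"n_topics_ge_{sig_threshold:g}"
    return df


def max_score_histogram(doc_topic: np.ndarray, bins: int = 50,
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of per-document maximum topic scores."""
    return np.histogram(doc_topic.max(axis=1), bins=bins, range=(0.0, 1.0))


def plot_max_score_histogram(doc_topic: np.ndarray, path: str,
                             bins: int = 50) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = max_score_histogram(doc_topic, bins=bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="white")
    ax.set_xlabel("maximum document topic score")
    ax.set_ylabel("documents")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
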