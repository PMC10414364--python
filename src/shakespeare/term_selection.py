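"""Selection of terms significant for the target group.

Two strategies mirror the two surveillance designs:

* **Ensemble** (group contrast): fit logistic regression (L2) and multinomial
  naive Bayes to label target vs. comparison documents, rank terms by LR
  positive-class coefficient and by NB log-probability ratio, and take the
  union with target-exclusive terms above a minimum count — capturing common,
  infrequent and rare target-significant terms.

* **Temporal** (recent period vs. prior period): intersect a classification
  set (union of the top-k LR positive-coefficient terms and the top-k NB
  lowest-log-ratio terms, models refit on the full two-period corpus without
  a split) with a frequency set (low-prevalence terms whose raw corpus count
  rose ≥30%, plus genuinely new terms, digit-only terms filtered out).

Ranking statistic for NB: log P(term | comparison) − log P(term | target)
with Laplace smoothing; the *lowest* values are the most target-favoring.
Ties break by (score, then term string) so selections are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB

from .exceptions import ConfigError
from .vectorize import TermMatrix

_DIGIT_TOKEN = re.compile(r"^[0-9]+$")


def is_digit_only(term: str) -> bool:
    """True iff every whitespace token of the term is all digits."""
    return all(_DIGIT_TOKEN.fullmatch(tok) for tok in term.split())


@dataclass
class EnsembleConfig:
    k_lr: int = 20000
    k_nb: int = 20000
    exclusive_min_count: int = 3
    lr_margin: float = 1e-6       # LR coefficient must exceed this
    nb_margin: float = 1e-6       # NB log ratio must be below −this
    C: float = 1.0
    nb_alpha: float = 1.0
    binary_features: bool = False
    max_iter: int = 1000
    seed: int = 0


@dataclass
class TemporalConfig:
    top_k: int = 5000
    low_prevalence: float = 0.10      # period-2 document-frequency ceiling
    increase_factor: float = 1.3      # period-3 raw count >= factor * period-2
    digit_filter: bool = True         # drop digit-only new terms
    normalize_counts: bool = False    # per-document-normalized increase rule
    C: float = 1.0
    nb_alpha: float = 1.0
    binary_features: bool = False
    max_iter: int = 1000
    seed: int = 0


@dataclass
class TermSelectionResult:
    selected: List[str]
    diagnostics: pd.DataFrame           # per-term scores, frequencies, flags
    stage_counts: Dict[str, int] = field(default_factory=dict)
    strategy: str = ""


@dataclass
class ClassifierEvalReport:
    lr_weighted_f1: float
    nb_weighted_f1: float
    lr_per_class: Dict[str, Dict[str, float]]
    nb_per_class: Dict[str, Dict[str, float]]
    split_fraction: float
    seed: int


def _check_shared_vocabulary(a: TermMatrix, b: TermMatrix) -> None:
    if a.vocabulary.terms != b.vocabulary.terms:
        raise ConfigError("matrices must share one vocabulary")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ConfigError("both groups/periods must contain documents")


def _fit_models(X: sp.csr_matrix, y: np.ndarray, C: float, alpha: float,
                max_iter: int) -> Tuple[np.ndarray, np.ndarray]:
    """Return (LR positive-class coefficients, NB log P(t|0) − log P(t|1))."""
    lr = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")
    lr.fit(X, y)
    nb = MultinomialNB(alpha=alpha)
    nb.fit(X, y)
    flp = nb.feature_log_prob_          # rows ordered by sorted classes [0, 1]
    return lr.coef_.ravel(), flp[0] - flp[1]


def _top_k_desc(scores: np.ndarray, terms: Sequence[str], k: int,
                floor: float) -> Set[str]:
    """Top-k terms by descending score among scores > floor; ties by term."""
    order = sorted((j for j in range(len(terms)) if scores[j] > floor),
                   key=lambda j: (-scores[j], terms[j]))
    return {terms[j] for j in order[:k]}


def _bottom_k_asc(scores: np.ndarray, terms: Sequence[str], k: int,
                  ceiling: float) -> Set[str]:
    """Bottom-k terms by ascending score among scores < ceiling; ties by term."""
    order = sorted((j for j in range(len(terms)) if scores[j] < ceiling),
                   key=lambda j: (scores[j], terms[j]))
    return {terms[j] for j in order[:k]}


def select_terms_ensemble(target: TermMatrix, comparison: TermMatrix,
                          config: Optional[EnsembleConfig] = None,
                          ) -> TermSelectionResult:
    """Classifier-ensemble term selection for a group contrast."""
    if config is None:
        config = EnsembleConfig()
    _check_shared_vocabulary(target, comparison)
    terms = target.vocabulary.terms

    X = sp.vstack([target.counts, comparison.counts]).tocsr()
    if config.binary_features:
        X = (X > 0).astype(np.int64)
    y = np.r_[np.ones(target.shape[0], dtype=int),
              np.zeros(comparison.shape[0], dtype=int)]

    lr_coef, nb_ratio = _fit_models(X, y, config.C, config.nb_alpha,
                                    config.max_iter)

    lr_set = _top_k_desc(lr_coef, terms, config.k_lr, config.lr_margin)
    nb_set = _bottom_k_asc(nb_ratio, terms, config.k_nb, -config.nb_margin)

    count_t = target.term_counts()
    count_c = comparison.term_counts()
    exclusive = {terms[j] for j in range(len(terms))
                 if count_c[j] == 0 and count_t[j] >= config.exclusive_min_count}

    selected = sorted(lr_set | nb_set | exclusive)
    diag = pd.DataFrame({
        "term": terms,
        "lr_coef": lr_coef,
        "nb_log_ratio": nb_ratio,
        "count_target": count_t,
        "count_comparison": count_c,
        "df_target": target.doc_frequency(),
        "df_comparison": comparison.doc_frequency(),
        "flag_lr": [t in lr_set for t in terms],
        "flag_nb": [t in nb_set for t in terms],
        "flag_exclusive": [t in exclusive for t in terms],
    }).set_index("term")
    diag["selected"] = diag[["flag_lr", "flag_nb", "flag_exclusive"]].any(axis=1)
    return TermSelectionResult(
        selected=selected,
        diagnostics=diag,
        stage_counts={"vocabulary": len(terms), "lr": len(lr_set),
                      "nb": len(nb_set), "exclusive": len(exclusive),
                      "selected": len(selected)},
        strategy="ensemble",
    )


def select_terms_temporal(period2: TermMatrix, period3: TermMatrix,
                          config: Optional[TemporalConfig] = None,
                          ) -> TermSelectionResult:
    """Classification ∩ frequency-analysis term selection between two periods.

    period3 (the recent period) is the positive class.
    """
    if config is None:
        config = TemporalConfig()
    _check_shared_vocabulary(period2, period3)
    terms = period2.vocabulary.terms

    # (a) classification set, refit without a train-test split
    X = sp.vstack([period2.counts, period3.counts]).tocsr()
    if config.binary_features:
        X = (X > 0).astype(np.int64)
    y = np.r_[np.zeros(period2.shape[0], dtype=int),
              np.ones(period3.shape[0], dtype=int)]
    lr_coef, nb_ratio = _fit_models(X, y, config.C, config.nb_alpha,
                                    config.max_iter)
    lr_set = _top_k_desc(lr_coef, terms, config.top_k, 0.0)
    nb_set = _bottom_k_asc(nb_ratio, terms, config.top_k, np.inf)
    classification = lr_set | nb_set

    # (b) frequency set
    df2 = period2.doc_frequency()
    c2 = period2.term_counts()
    c3 = period3.term_counts()
    n2 = period2.shape[0]
    if config.normalize_counts:
        rate2 = c2 / n2
        rate3 = c3 / period3.shape[0]
        increased = rate3 >= config.increase_factor * rate2
    else:
        increased = c3 >= config.increase_factor * c2
    low_prev_increasing = {
        terms[j] for j in range(len(terms))
        if c2[j] >= 1 and df2[j] < config.low_prevalence * n2 and increased[j]
    }
    new_terms = {terms[j] for j in range(len(terms)) if c2[j] == 0 and c3[j] > 0}
    if config.digit_filter:
        new_terms = {t for t in new_terms if not is_digit_only(t)}
    frequency = low_prev_increasing | new_terms

    selected = sorted(classification & frequency)
    diag = pd.DataFrame({
        "term": terms,
        "lr_coef": lr_coef,
        "nb_log_ratio": nb_ratio,
        "count_period2": c2,
        "count_period3": c3,
        "df_period2": df2,
        "df_period3": period3.doc_frequency(),
        "flag_classification": [t in classification for t in terms],
        "flag_frequency_increase": [t in low_prev_increasing for t in terms],
        "flag_new_term": [t in new_terms for t in terms],
    }).set_index("term")
    diag["selected"] = diag.index.isin(selected)
    return TermSelectionResult(
        selected=selected,
        diagnostics=diag,
        stage_counts={
            "vocabulary": len(terms),
            "lr": len(lr_set),
            "nb": len(nb_set),
            "classification_union": len(classification),
            "frequency_increase": len(low_prev_increasing),
            "new_terms": len(new_terms),
            "frequency_union": len(frequency),
            "selected": len(selected),
        },
        strategy="temporal",
    )


def evaluate_classifiers(period2: TermMatrix, period3: TermMatrix,
                         split_fraction: float = 0.25, seed: int = 0,
                         ) -> ClassifierEvalReport:
    """Held-out weighted F1 for LR (L2) and multinomial NB on the two periods."""
    _check_shared_vocabulary(period2, period3)
    if not 0.0 < split_fraction < 1.0:
        raise ConfigError("split_fraction must be in (0, 1)")
    if min(period2.shape[0], period3.shape[0]) < 2:
        raise ConfigError("each period needs at least 2 documents for a "
                          "stratified split")
    X = sp.vstack([period2.counts, period3.counts]).tocsr()
    y = np.r_[np.zeros(period2.shape[0], dtype=int),
              np.ones(period3.shape[0], dtype=int)]
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=split_fraction, stratify=y, random_state=seed)
    except ValueError as exc:
        raise ConfigError(f"degenerate split: {exc}") from exc

    lr = LogisticRegression(C=1.0, max_iter=1000, solver="lbfgs").fit(X_tr, y_tr)
    nb = MultinomialNB(alpha=1.0).fit(X_tr, y_tr)

    def per_class(y_pred: np.ndarray) -> Dict[str, Dict[str, float]]:
        prec, rec, _, _ = precision_recall_fscore_support(
            y_te, y_pred, labels=[0, 1], zero_division=0)
        return {str(c): {"precision": float(prec[i]), "recall": float(rec[i])}
                for i, c in enumerate([0, 1])}

    lr_pred = lr.predict(X_te)
    nb_pred = nb.predict(X_te)
    return ClassifierEvalReport(
        lr_weighted_f1=float(f1_score(y_te, lr_pred, average="weighted")),
        nb_weighted_f1=float(f1_score(y_te, nb_pred, average="weighted")),
        lr_per_class=per_class(lr_pred),
        nb_per_class=per_class(nb_pred),
        split_fraction=split_fraction,
        seed=seed,
    )


def trim_matrix(matrix: TermMatrix, selected: Sequence[str]) -> TermMatrix:
    """Restrict matrix columns to the selected terms (counts unchanged)."""
    selected = list(selected)
    if not selected:
        raise ConfigError("empty term selection: nothing to trim to")
    return matrix.restrict(selected)
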