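"""Term-selection contracts: ensemble, temporal rules, classifier evaluation."""

import numpy as np
import pytest

import shakespeare as sk
from shakespeare.term_selection import is_digit_only
from shakespeare.vectorize import Vocabulary, vectorize_documents

from conftest import group_matrices, prepare_documents


def _matrix(docs, vocab_terms=None):
    vocab = Vocabulary(sorted(vocab_terms) if vocab_terms
                       else sorted({t for d in docs for t in d.split()}))
    return vectorize_documents(docs, vocab)


@pytest.fixture(scope="module")
def temporal_world():
    """Small two-period world: comparison rows = period 2, target = period 3."""
    notes, _, gt = sk.generate_cohort(
        sk.SynthConfig(n_admissions_per_group=100, seed=11))
    docs, texts = prepare_documents(notes, gt)
    _, p3, p2 = group_matrices(docs, texts, max_n=1)
    return p2, p3


# --- ensemble ---------------------------------------------------------------

def test_identical_corpora_select_nothing():
    docs = ["a b c d", "b c e", "a e f f"]
    m = _matrix(docs)
    res = sk.select_terms_ensemble(m, m)
    assert res.selected == []


def test_single_group_is_error():
    m = _matrix(["a b"])
    empty = m.rows([])
    with pytest.raises(sk.ConfigError):
        sk.select_terms_ensemble(m, empty)


def test_mismatched_vocabulary_is_error():
    with pytest.raises(sk.ConfigError):
        sk.select_terms_ensemble(_matrix(["a b"]), _matrix(["a c"]))


def test_ensemble_recovers_injected_signal_terms():
    config = sk.SynthConfig(n_admissions_per_group=100, seed=21)
    notes, _, gt = sk.generate_cohort(config)
    docs, texts = prepare_documents(notes, gt)
    _, target, comparison = group_matrices(docs, texts, max_n=1)
    res = sk.select_terms_ensemble(
        target, comparison, sk.EnsembleConfig(k_lr=20, k_nb=20))
    signal = set(config.signal_terms)
    recall = len(set(res.selected) & signal) / len(signal)
    assert recall >= 0.8
    assert res.stage_counts["selected"] == len(res.selected)
    flags = res.diagnostics.loc[res.selected]
    assert flags[["flag_lr", "flag_nb", "flag_exclusive"]].any(axis=1).all()


def test_exclusive_path_catches_rare_target_only_terms():
    target = _matrix(["rareterm x y", "rareterm y", "rareterm x", "x y"],
                     vocab_terms=["rareterm", "x", "y"])
    comparison = _matrix(["x y", "x", "y y"], vocab_terms=["rareterm", "x", "y"])
    res = sk.select_terms_ensemble(
        target, comparison,
        sk.EnsembleConfig(k_lr=0, k_nb=0, exclusive_min_count=3))
    assert res.selected == ["rareterm"]


def test_ensemble_deterministic(temporal_world):
    p2, p3 = temporal_world
    cfg = sk.EnsembleConfig(k_lr=30, k_nb=30)
    assert sk.select_terms_ensemble(p3, p2, cfg).selected == \
           sk.select_terms_ensemble(p3, p2, cfg).selected


# --- temporal ---------------------------------------------------------------

def brute_force_frequency_set(p2, p3, low=0.10, factor=1.3, digit_filter=True):
    """Literal re-scan of the frequency rules over the vocabulary."""
    terms = p2.vocabulary.terms
    df2 = p2.doc_frequency()
    c2, c3 = p2.term_counts(), p3.term_counts()
    n2 = p2.shape[0]
    out = set()
    for j, t in enumerate(terms):
        if c2[j] >= 1 and df2[j] / n2 < low and c3[j] >= factor * c2[j]:
            out.add(t)
        if c2[j] == 0 and c3[j] > 0:
            if not (digit_filter and is_digit_only(t)):
                out.add(t)
    return out


def test_temporal_frequency_rules_match_brute_force(temporal_world):
    p2, p3 = temporal_world
    res = sk.select_terms_temporal(p2, p3)
    diag = res.diagnostics
    freq_set = set(diag.index[diag["flag_frequency_increase"]
                              | diag["flag_new_term"]])
    assert freq_set == brute_force_frequency_set(p2, p3)


def test_temporal_selected_is_intersection(temporal_world):
    p2, p3 = temporal_world
    res = sk.select_terms_temporal(p2, p3)
    diag = res.diagnostics
    classification = set(diag.index[diag["flag_classification"]])
    frequency = set(diag.index[diag["flag_frequency_increase"]
                               | diag["flag_new_term"]])
    assert set(res.selected) == classification & frequency
    assert set(res.selected) <= classification
    assert set(res.selected) <= frequency


def test_digit_only_new_terms_are_filtered():
    vocab = ["2007", "newdrug", "x"]
    p2 = _matrix(["x x", "x"], vocab_terms=vocab)
    p3 = _matrix(["2007 newdrug x", "2007 x"], vocab_terms=vocab)
    res = sk.select_terms_temporal(p2, p3)
    diag = res.diagnostics
    assert not diag.loc["2007", "flag_new_term"]
    assert diag.loc["newdrug", "flag_new_term"]
    no_filter = sk.select_terms_temporal(p2, p3,
                                         sk.TemporalConfig(digit_filter=False))
    assert no_filter.diagnostics.loc["2007", "flag_new_term"]


def test_digit_only_token_rule():
    assert is_digit_only("2007")
    assert is_digit_only("12 345")
    assert not is_digit_only("37.2")
    assert not is_digit_only("x 12")


def test_temporal_empty_period_is_error(temporal_world):
    p2, p3 = temporal_world
    with pytest.raises(sk.ConfigError):
        sk.select_terms_temporal(p2.rows([]), p3)


# --- classifier evaluation ----------------------------------------------------

def test_perfectly_separable_groups_reach_f1_one():
    rng = np.random.default_rng(3)
    vocab = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    p2 = _matrix([" ".join(rng.choice(vocab[:10], 20)) for _ in range(40)],
                 vocab_terms=vocab)
    p3 = _matrix([" ".join(rng.choice(vocab[10:], 20)) for _ in range(40)],
                 vocab_terms=vocab)
    report = sk.evaluate_classifiers(p2, p3, split_fraction=0.25, seed=0)
    assert report.lr_weighted_f1 == 1.0
    assert report.nb_weighted_f1 == 1.0


def test_indistinguishable_groups_near_chance():
    """Both periods drawn from one distribution: held-out weighted F1 sits
    near the 50/50 chance level, far below separable performance."""
    rng = np.random.default_rng(4)
    vocab = [f"w{i}" for i in range(30)]
    docs = [" ".join(rng.choice(vocab, 25)) for _ in range(120)]
    p2 = _matrix(docs[:60], vocab_terms=vocab)
    p3 = _matrix(docs[60:], vocab_terms=vocab)
    report = sk.evaluate_classifiers(p2, p3, split_fraction=0.3, seed=1)
    assert report.lr_weighted_f1 < 0.7
    assert report.nb_weighted_f1 < 0.7


def test_degenerate_split_is_error():
    m = _matrix(["a", "b"])
    with pytest.raises(sk.ConfigError):
        sk.evaluate_classifiers(m.rows([0]), m.rows([1]), 0.5, 0)


# --- trim ---------------------------------------------------------------------

def test_trim_full_vocabulary_is_identity(temporal_world):
    p2, _ = temporal_world
    trimmed = sk.trim_matrix(p2, p2.vocabulary.terms)
    assert (trimmed.counts != p2.counts).nnz == 0


def test_trim_empty_selection_is_error(temporal_world):
    p2, _ = temporal_world
    with pytest.raises(sk.ConfigError):
        sk.trim_matrix(p2, [])


def test_trim_conserves_column_sums(temporal_world):
    p2, _ = temporal_world
    rng = np.random.default_rng(1)
    keep = sorted(rng.choice(p2.vocabulary.terms,
                             size=len(p2.vocabulary) // 2, replace=False))
    trimmed = sk.trim_matrix(p2, keep)
    full = dict(zip(p2.vocabulary.terms, p2.term_counts()))
    assert dict(zip(trimmed.vocabulary.terms, trimmed.term_counts())) == \
           {t: full[t] for t in keep}
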