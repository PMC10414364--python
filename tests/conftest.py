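"""Shared fixtures: seeded synthetic cohorts and prepared corpora."""

from __future__ import annotations

from typing import List, Tuple

import pandas as pd
import pytest

import shakespeare as sk


def notes_to_records(notes: pd.DataFrame) -> List[sk.NoteRecord]:
    return [sk.NoteRecord(r.ADMISSION_ID, float(r.AGE),
                          pd.Timestamp(r.CHARTTIME), r.CATEGORY, r.TEXT)
            for r in notes.itertuples(index=False)]


def prepare_documents(notes: pd.DataFrame, gt: sk.GroundTruth,
                      min_age: float = 16,
                      pii_mask: str = "[**PII**]",
                      ) -> Tuple[List[sk.AdmissionDocument], List[str]]:
    """Standard preprocessing path: filter, assemble, dedup, normalize."""
    records = sk.filter_cohort(notes_to_records(notes), min_age)
    docs = sk.assemble_documents(records, labels=gt.groups)
    texts = [sk.normalize_text(sk.dedup_document(d.text), pii_mask)
             for d in docs]
    return docs, texts


def group_matrices(docs, texts, max_n: int = 1,
                   ) -> Tuple[sk.TermMatrix, sk.TermMatrix, sk.TermMatrix]:
    """Vectorize and split rows into (full, target, comparison) matrices."""
    vocab = sk.build_vocabulary(texts, max_n=max_n)
    matrix = sk.vectorize_documents(texts, vocab,
                                    doc_ids=[d.admission_id for d in docs])
    tgt = [i for i, d in enumerate(docs) if d.group == "target"]
    cmp_ = [i for i, d in enumerate(docs) if d.group == "comparison"]
    return matrix, matrix.rows(tgt), matrix.rows(cmp_)


@pytest.fixture(scope="session")
def standard_cohort():
    """The default benchmark world (300 admissions/group, seed 1)."""
    config = sk.SynthConfig(seed=1)
    notes, codes, gt = sk.generate_cohort(config)
    return config, notes, codes, gt


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 60-admissions-per-group world for unit tests."""
    config = sk.SynthConfig(n_admissions_per_group=60, seed=5)
    notes, codes, gt = sk.generate_cohort(config)
    return config, notes, codes, gt


@pytest.fixture(scope="session")
def lda_fit_45():
    """A 45-topic fit on a 200-document corpus that includes one document
    with zero in-vocabulary terms (appended empty text)."""
    config = sk.SynthConfig(n_admissions_per_group=100, n_under_16=0, seed=7)
    notes, _, gt = sk.generate_cohort(config)
    docs, texts = prepare_documents(notes, gt)
    vocab = sk.build_vocabulary(texts, max_n=1)
    all_texts = texts + [""]
    matrix = sk.vectorize_documents(
        all_texts, vocab,
        doc_ids=[d.admission_id for d in docs] + ["EMPTY"])
    result = sk.fit_lda(matrix, K=45, seed=3)
    return matrix, result
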