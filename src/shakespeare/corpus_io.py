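"""Read notes/codes tables, filter the cohort, assemble admission documents.

One admission's notes are concatenated chronologically into a single document;
discharge summaries alone miss information, so all available notes are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .exceptions import SchemaError

NOTES_COLUMNS = ["ADMISSION_ID", "AGE", "CHARTTIME", "CATEGORY", "TEXT"]
CODES_COLUMNS = ["ADMISSION_ID", "CODE_TYPE", "CODE"]


@dataclass(frozen=True)
class NoteRecord:
    admission_id: str
    age: float
    charttime: pd.Timestamp
    category: str
    text: str


@dataclass
class AdmissionDocument:
    admission_id: str
    text: str
    note_count: int
    first_charttime: pd.Timestamp
    group: Optional[str] = None


def load_notes(path: str | Path) -> List[NoteRecord]:
    """Load a notes CSV into NoteRecords, in file order.

    Malformed rows (empty admission id, unparseable timestamp or age) are
    collected and reported together with their 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in NOTES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records: List[NoteRecord] = []
    problems: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        adm = getattr(row, "ADMISSION_ID")
        ts = pd.to_datetime(getattr(row, "CHARTTIME"), errors="coerce")
        try:
            age = float(getattr(row, "AGE"))
        except ValueError:
            age = float("nan")
        if not adm:
            problems.append(f"row {i}: empty ADMISSION_ID")
        elif pd.isna(ts):
            problems.append(f"row {i}: unparseable CHARTTIME "
                            f"{getattr(row, 'CHARTTIME')!r}")
        elif age != age:  # NaN
            problems.append(f"row {i}: unparseable AGE {getattr(row, 'AGE')!r}")
        else:
            records.append(NoteRecord(adm, age, ts, getattr(row, "CATEGORY"),
                                      getattr(row, "TEXT")))
    if problems:
        raise SchemaError(f"{path}: malformed rows: " + "; ".join(problems))
    return records


def load_codes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CODES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df[CODES_COLUMNS]


def load_labels(path: str | Path) -> Dict[str, str]:
    """Two-column admission → group label mapping (ADMISSION_ID, GROUP)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise SchemaError(f"{path}: label mapping needs two columns, got {cols}")
    return dict(zip(df[cols[0]], df[cols[1]]))


def filter_cohort(records: Sequence[NoteRecord], min_age: float = 16,
                  ) -> List[NoteRecord]:
    """Drop entire admissions whose patient age is below ``min_age``.

    Admissions without notes never appear in a notes table, so they are
    absent from the output by construction.
    """
    if min_age < 0:
        raise ValueError("min_age must be >= 0")
    young = {r.admission_id for r in records if r.age < min_age}
    return [r for r in records if r.admission_id not in young]


def assemble_documents(records: Sequence[NoteRecord],
                       labels: Optional[Dict[str, str]] = None,
                       ) -> List[AdmissionDocument]:
    """One document per admission: notes sorted by charttime (stable on ties,
    i.e. input order), joined with a newline. Documents are returned sorted
    by admission id for reproducible downstream ordering."""
    by_adm: Dict[str, List[NoteRecord]] = {}
    for r in records:
        by_adm.setdefault(r.admission_id, []).append(r)
    docs: List[AdmissionDocument] = []
    for adm in sorted(by_adm):
        notes = sorted(by_adm[adm], key=lambda r: r.charttime)  # stable
        docs.append(AdmissionDocument(
            admission_id=adm,
            text="\n".join(n.text for n in notes),
            note_count=len(notes),
            first_charttime=notes[0].charttime,
            group=labels.get(adm) if labels else None,
        ))
    return docs


def write_documents(docs: Sequence[AdmissionDocument], path: str | Path) -> None:
    pd.DataFrame({
        "ADMISSION_ID": [d.admission_id for d in docs],
        "GROUP": [d.group or "" for d in docs],
        "FIRST_CHARTTIME": [d.first_charttime.isoformat() for d in docs],
        "NOTE_COUNT": [d.note_count for d in docs],
        "TEXT": [d.text for d in docs],
    }).to_csv(path, index=False, lineterminator="\n")


def read_documents(path: str | Path) -> List[AdmissionDocument]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = {"ADMISSION_ID", "GROUP", "FIRST_CHARTTIME", "NOTE_COUNT", "TEXT"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return [AdmissionDocument(r.ADMISSION_ID, r.TEXT, int(r.NOTE_COUNT),
                              pd.Timestamp(r.FIRST_CHARTTIME),
                              r.GROUP or None)
            for r in df.itertuples(index=False)]
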