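"""Synthetic NOTEEVENTS-like corpora with known ground truth.

Real critical-care note tables are credential-restricted, so every downstream
stage is exercised against generated corpora that emulate the properties that
matter to the method: several note types per admission, boilerplate sentences
replicated within an admission, PII mask strings, misspellings and
abbreviations, group-specific signal terms injected at controlled document
rates, and terms whose document prevalence follows a linear per-quarter trend.

The generator's defaults are the standard benchmark used throughout the test
suite: 300 admissions per group, 20 signal terms at document rates 0.60
(target) vs 0.05 (comparison), duplicate fraction 0.30, 28 calendar quarters
starting July 2001.  One integer seed drives all randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dedup import ABBREVIATIONS, normalize_key
from .exceptions import ConfigError

# ---------------------------------------------------------------------------
# lexicon fixture: common words + clinical abbreviations + misspellings
# ---------------------------------------------------------------------------

_BASE_LEXICON: List[str] = [
    # plain / connective words (Zipf head)
    "the", "and", "of", "to", "on", "at", "in", "is", "was", "with", "for",
    "per", "as", "from", "no", "will", "this", "today", "overnight", "am",
    # clinical vocabulary
    "patient", "pt", "stable", "alert", "oriented", "afebrile", "plan",
    "continue", "monitor", "wean", "vent", "intubated", "extubated",
    "sedated", "propofol", "fentanyl", "morphine", "lasix", "diuresis",
    "foley", "skin", "intact", "edema", "bilateral", "breath", "sounds",
    "clear", "coarse", "crackles", "lungs", "chest", "cxr", "pending",
    "labs", "cbc", "lytes", "repleted", "potassium", "magnesium", "sodium",
    "glucose", "insulin", "sliding", "scale", "bp", "hr", "rr", "sats",
    "spo2", "temp", "map", "cvp", "remains", "tolerating", "diet",
    "advanced", "ambulating", "transferred", "admitted", "discharged",
    "family", "meeting", "updated", "consult", "placed", "removed",
    "started", "stopped", "increased", "decreased", "improved", "worsened",
    "unchanged", "noted", "denies", "reports", "pain", "controlled",
    "given", "held", "due", "secondary", "likely", "possible", "concern",
    "status", "post", "surgery", "incision", "dressing", "drainage",
    "wound", "site", "clean", "dry", "acute", "events", "follow", "up",
    "cough", "fever", "wbc", "cultures", "antibiotics", "levofloxacin",
    "ct", "mri", "head", "abd", "soft", "nontender", "bowel", "regimen",
    # abbreviations (punctuation-bearing tokens are kept on purpose)
    "s/p", "w/", "c/o", "r/o", "y/o", "hx", "dx", "tx", "prn", "bid",
    "tid", "q4h", "q6h", "npo", "po", "iv", "ivf", "gtt", "abg", "ett",
    "ngt", "picc", "ekg", "echo", "cath", "icu", "micu", "sicu", "ccu",
    "sob", "cp", "ext", "neuro", "gi", "gu", "dr.",
    # misspellings
    "recieved", "occured", "diarhea", "hemmorage", "patinet", "abdomin",
    "asess", "foly", "stabel", "febril",
]

_DIGIT_POOL = [
    "2007", "2008", "120", "80", "98", "101", "37.2", "0.9", "1.5",
    "325", "40", "100", "14", "7", "2",
]

DEFAULT_SIGNAL_TERMS: List[str] = [
    "trali", "taco", "hemolysis", "anaphylaxis", "urticaria", "rigors",
    "hypoxemia", "alloantibody", "febrile", "chills", "pruritus",
    "flushing", "bronchospasm", "hemoglobinuria", "transfusion", "prbc",
    "ffp", "platelets", "crossmatch", "reaction",
]

#: (token, per-quarter document-prevalence slope, baseline prevalence)
DEFAULT_TREND_TERMS: List[Tuple[str, float, float]] = [
    ("heparin", 0.005, 0.05),
    ("hypotension", 0.004, 0.08),
    ("allergy", -0.002, 0.12),
]

_CATEGORIES = ["Nursing", "Physician", "Radiology", "Discharge summary"]

_CODE_POOL = [
    ("ICD9_PROC", "38.93"), ("ICD9_PROC", "96.71"), ("ICD9_DX", "486"),
    ("ICD9_DX", "584.9"), ("ICD9_DX", "V58.61"), ("ICD9_DX", "E934.2"),
    ("ICD9_PROC", "88.56"), ("ICD9_DX", "995.0"), ("ICD9_PROC", "37.23"),
    ("ICD9_DX", "428.0"),
]
#: every target-group admission carries this transfusion procedure code
_TARGET_CODE = ("ICD9_PROC", "99.04")

#: first day of quarter 0 (study window July 2001 – June 2008 = 28 quarters)
QUARTER0 = pd.Timestamp("2001-07-01")

NOTES_COLUMNS = ["ADMISSION_ID", "AGE", "CHARTTIME", "CATEGORY", "TEXT"]
CODES_COLUMNS = ["ADMISSION_ID", "CODE_TYPE", "CODE"]


# ---------------------------------------------------------------------------
# configuration & ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Knobs of the generated world.  Defaults are the standard benchmark."""

    n_admissions_per_group: int = 300
    notes_per_admission: Tuple[int, int] = (2, 5)
    background_vocab_size: int = 200
    signal_terms: Sequence[str] = field(default_factory=lambda: list(DEFAULT_SIGNAL_TERMS))
    signal_rate_target: float = 0.60
    signal_rate_comparison: float = 0.05
    duplicate_fraction: float = 0.30
    trend_terms: Sequence[Tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_TREND_TERMS))
    n_quarters: int = 28
    digit_noise_rate: float = 0.15
    pii_mask_string: str = "[**PII**]"
    age_range: Tuple[int, int] = (16, 90)
    n_under_16: int = 1
    list_block_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "signal_rate_target": self.signal_rate_target,
            "signal_rate_comparison": self.signal_rate_comparison,
            "duplicate_fraction": self.duplicate_fraction,
            "digit_noise_rate": self.digit_noise_rate,
            "list_block_rate": self.list_block_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.background_vocab_size < 1:
            raise ConfigError("background_vocab_size must be >= 1")
        if self.n_admissions_per_group < 1:
            raise ConfigError("n_admissions_per_group must be >= 1")
        if self.n_quarters < 1:
            raise ConfigError("n_quarters must be >= 1")
        lo, hi = self.notes_per_admission
        if not (1 <= lo <= hi):
            raise ConfigError("notes_per_admission must satisfy 1 <= lo <= hi")
        if self.signal_terms and not self.signal_rate_target > self.signal_rate_comparison:
            raise ConfigError(
                "signal_rate_target must exceed signal_rate_comparison "
                "when signal terms are requested")
        for entry in self.trend_terms:
            if len(entry) != 3:
                raise ConfigError("trend_terms entries are (token, slope, baseline)")
            _, slope, base = entry
            if not 0.0 <= base <= 1.0:
                raise ConfigError(f"trend baseline must be in [0, 1], got {base}")


@dataclass
class GroundTruth:
    """What was injected where; every injected element is recorded exactly once."""

    groups: Dict[str, str] = field(default_factory=dict)
    signal_terms: Dict[str, List[str]] = field(default_factory=dict)
    trend_slopes: Dict[str, float] = field(default_factory=dict)
    trend_presence: Dict[str, List[str]] = field(default_factory=dict)
    duplicates: Dict[str, List[str]] = field(default_factory=dict)
    quarter: Dict[str, int] = field(default_factory=dict)
    under_16: List[str] = field(default_factory=list)
    zero_note: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _build_lexicon(config: SynthConfig) -> List[str]:
    reserved = set(config.signal_terms) | {t for t, _, _ in config.trend_terms}
    reserved.add(config.pii_mask_string)
    lexicon = [w for w in dict.fromkeys(_BASE_LEXICON) if w not in reserved]
    i = 0
    while len(lexicon) < config.background_vocab_size:
        cand = f"term{i:04d}"
        if cand not in reserved:
            lexicon.append(cand)
        i += 1
    return lexicon[: config.background_vocab_size]


class _Sentence:
    """Mutable sentence under construction: tokens + terminator."""

    __slots__ = ("tokens", "newline", "list_prefix")

    def __init__(self, tokens: List[str], newline: bool, list_prefix: str = ""):
        self.tokens = tokens
        self.newline = newline
        self.list_prefix = list_prefix

    def render(self) -> str:
        body = self.list_prefix + " ".join(self.tokens)
        if self.list_prefix or self.newline:
            return body + "\n"
        if body.endswith("."):
            # final token already period-bearing ("dr."): reads as an
            # abbreviation mid-line, so end the line to keep segmentation
            # context-free
            return body + "\n"
        if (body.split()[-1] + ".").lower() in ABBREVIATIONS:
            return body + "\n"  # "no." would read as an abbreviation
        return body + ". "

    def key(self) -> str:
        return normalize_key(self.render())


def _fresh_sentence(rng: np.random.Generator, lexicon: List[str],
                    probs: np.ndarray, config: SynthConfig,
                    seen: set) -> _Sentence:
    for attempt in range(25):
        length = int(rng.integers(4, 10))
        tokens = [lexicon[i] for i in rng.choice(len(lexicon), size=length, p=probs)]
        if rng.random() < config.digit_noise_rate:
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens.insert(pos, _DIGIT_POOL[int(rng.integers(0, len(_DIGIT_POOL)))])
        sent = _Sentence(tokens, newline=bool(rng.random() < 0.3))
        if sent.key() not in seen:
            seen.add(sent.key())
            return sent
    # pathological tiny vocabularies: disambiguate explicitly
    sent.tokens.append(f"u{len(seen)}")
    seen.add(sent.key())
    return sent


def _list_block(rng: np.random.Generator, lexicon: List[str], probs: np.ndarray,
                seen: set) -> List[_Sentence]:
    n_items = int(rng.integers(2, 5))
    items = []
    for j in range(n_items):
        for attempt in range(25):
            length = int(rng.integers(2, 4))
            tokens = [lexicon[i] for i in rng.choice(len(lexicon), size=length, p=probs)]
            sent = _Sentence(tokens, newline=True, list_prefix=f"{j + 1}. ")
            if sent.key() not in seen:
                seen.add(sent.key())
                items.append(sent)
                break
        else:
            sent.tokens.append(f"u{len(seen)}")
            seen.add(sent.key())
            items.append(sent)
    return items


def _position_keeps_segmentation(note: List[_Sentence], pos: int,
                                 copy: _Sentence) -> bool:
    """A replicate copy must re-segment to the same unit as its original:
    list items must start a line, and a period-terminated sentence must not
    butt up against a following list item."""
    if copy.list_prefix:
        if pos == 0:
            return True  # notes are newline-joined, so note starts are line starts
        prev = note[pos - 1]
        return bool(prev.newline or prev.list_prefix)
    if not copy.newline and pos < len(note) and note[pos].list_prefix:
        return False
    return True


def _insert_copy(notes: List[List[_Sentence]], copy: _Sentence,
                 rng: np.random.Generator) -> None:
    for _ in range(30):
        note = notes[int(rng.integers(0, len(notes)))]
        pos = int(rng.integers(0, len(note) + 1))
        if _position_keeps_segmentation(note, pos, copy):
            note.insert(pos, copy)
            return
    if copy.list_prefix:
        notes[0].insert(0, copy)
    else:
        notes[-1].append(copy)


def generate_cohort(config: SynthConfig | None = None,
                    ) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (notes table, codes table, ground truth) for one seeded world.

    The notes table has one row per note (ADMISSION_ID, AGE, CHARTTIME,
    CATEGORY, TEXT); the codes table one row per admission code.  Fixed seed
    gives byte-identical tables.
    """
    if config is None:
        config = SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    lexicon = _build_lexicon(config)
    ranks = np.arange(1, len(lexicon) + 1, dtype=float)
    probs = (1.0 / ranks) / (1.0 / ranks).sum()

    n = config.n_admissions_per_group
    adm_ids = [f"T{i:05d}" for i in range(n)] + [f"C{i:05d}" for i in range(n)]
    gt = GroundTruth()
    gt.trend_slopes = {t: s for t, s, _ in config.trend_terms}
    gt.trend_presence = {t: [] for t, _, _ in config.trend_terms}

    n_under = min(config.n_under_16, len(adm_ids))
    under_idx = set(rng.choice(len(adm_ids), size=n_under, replace=False).tolist())
    gt.under_16 = sorted(adm_ids[i] for i in under_idx)

    notes_rows: List[dict] = []
    codes_rows: List[dict] = []

    for idx, adm in enumerate(adm_ids):
        group = "target" if adm.startswith("T") else "comparison"
        gt.groups[adm] = group
        if idx in under_idx:
            age = int(rng.integers(1, 16))
        else:
            age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        quarter = int(rng.integers(0, config.n_quarters))
        gt.quarter[adm] = quarter

        n_notes = int(rng.integers(config.notes_per_admission[0],
                                   config.notes_per_admission[1] + 1))
        seen: set = set()
        notes: List[List[_Sentence]] = []
        for _ in range(n_notes):
            n_sent = int(rng.integers(4, 9))
            note = [_fresh_sentence(rng, lexicon, probs, config, seen)
                    for _ in range(n_sent)]
            if rng.random() < config.list_block_rate:
                note[-1].newline = True  # list blocks start on a fresh line
                note.extend(_list_block(rng, lexicon, probs, seen))
            notes.append(note)

        def inject(token: str) -> None:
            # never inject sentence-final: the period would fuse with the
            # token ("hemolysis.") and split its document frequency
            note = notes[int(rng.integers(0, len(notes)))]
            targets = [s for s in note if not s.list_prefix] or note
            sent = targets[int(rng.integers(0, len(targets)))]
            sent.tokens.insert(int(rng.integers(0, len(sent.tokens))), token)

        rate = (config.signal_rate_target if group == "target"
                else config.signal_rate_comparison)
        injected = [t for t in config.signal_terms if rng.random() < rate]
        for term in injected:
            inject(term)
        if injected:
            gt.signal_terms[adm] = injected

        for token, slope, base in config.trend_terms:
            p = float(np.clip(base + slope * quarter, 0.0, 1.0))
            if rng.random() < p:
                inject(token)
                gt.trend_presence[token].append(adm)

        masked = [bool(rng.random() < 0.3) for _ in notes]
        for note, has_mask in zip(notes, masked):
            if has_mask:
                targets = [s for s in note if not s.list_prefix] or note
                sent = targets[int(rng.integers(0, len(targets)))]
                sent.tokens.insert(int(rng.integers(0, len(sent.tokens))),
                                   config.pii_mask_string)

        # injections may (very rarely) collide with an existing sentence;
        # re-establish within-admission uniqueness before replication
        seen_final: set = set()
        for note in notes:
            for sent in note:
                while sent.key() in seen_final:
                    sent.tokens.append(f"u{len(seen_final)}")
                seen_final.add(sent.key())

        # replicate a fraction of sentences within the admission
        flat = [(ni, si) for ni, note in enumerate(notes) for si in range(len(note))]
        n_dup = int(round(config.duplicate_fraction * len(flat)))
        dup_keys: List[str] = []
        if n_dup:
            chosen = rng.choice(len(flat), size=min(n_dup, len(flat)), replace=False)
            originals = [notes[ni][si] for ni, si in
                         (flat[int(c)] for c in sorted(int(x) for x in chosen))]
            for original in originals:
                copy = _Sentence(list(original.tokens), original.newline,
                                 original.list_prefix)
                _insert_copy(notes, copy, rng)
                dup_keys.append(original.key())
        if dup_keys:
            gt.duplicates[adm] = dup_keys

        base_ts = (QUARTER0 + pd.DateOffset(months=3 * quarter)
                   + pd.Timedelta(days=int(rng.integers(0, 84)),
                                  hours=int(rng.integers(0, 24))))
        ts = base_ts
        for note in notes:
            text = "".join(s.render() for s in note).rstrip()
            notes_rows.append({
                "ADMISSION_ID": adm,
                "AGE": age,
                "CHARTTIME": ts.isoformat(),
                "CATEGORY": _CATEGORIES[int(rng.integers(0, len(_CATEGORIES)))],
                "TEXT": text,
            })
            ts = ts + pd.Timedelta(hours=int(rng.integers(1, 13)))

        codes = {_TARGET_CODE} if group == "target" else set()
        n_codes = int(rng.integers(1, 4))
        for c in rng.choice(len(_CODE_POOL), size=n_codes, replace=False):
            codes.add(_CODE_POOL[int(c)])
        for code_type, code in sorted(codes):
            codes_rows.append({"ADMISSION_ID": adm, "CODE_TYPE": code_type,
                               "CODE": code})

    # fodder: one admission with zero notes (codes table only)
    zero_adm = "Z00000"
    gt.groups[zero_adm] = "comparison"
    gt.zero_note = [zero_adm]
    gt.quarter[zero_adm] = 0
    codes_rows.append({"ADMISSION_ID": zero_adm, "CODE_TYPE": _CODE_POOL[0][0],
                       "CODE": _CODE_POOL[0][1]})

    notes = pd.DataFrame(notes_rows, columns=NOTES_COLUMNS)
    codes = pd.DataFrame(codes_rows, columns=CODES_COLUMNS)

    # guarantee the PII mask reaches at least 10% of notes
    has_mask = notes["TEXT"].str.contains(config.pii_mask_string, regex=False)
    need = int(np.ceil(0.10 * len(notes))) - int(has_mask.sum())
    if need > 0:
        for i in notes.index[~has_mask][:need]:
            notes.at[i, "TEXT"] = config.pii_mask_string + "\n" + notes.at[i, "TEXT"]

    return notes, codes, gt


def write_cohort(notes: pd.DataFrame, codes: pd.DataFrame, gt: GroundTruth,
                 out_dir: str | Path) -> Dict[str, Path]:
    """Serialize the cohort: notes.csv / codes.csv / ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": out / "notes.csv",
        "codes": out / "codes.csv",
        "ground_truth": out / "ground_truth.json",
    }
    notes.to_csv(paths["notes"], index=False, lineterminator="\n")
    codes.to_csv(paths["codes"], index=False, lineterminator="\n")
    paths["ground_truth"].write_text(gt.to_json())
    return paths
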