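"""Quarterly surveillance statistics and the group-contrast Fisher exact test.

A *presence criterion* is a small boolean expression evaluated per admission:

    word:"heparin" AND (code:"38.*" OR stay>=14)

Atoms are word presence (case-insensitive whole-token match on the normalized
document text; a trailing ``*`` permits any suffix), code presence in the
admission's code list (same ``*`` rule), and a length-of-stay predicate in
days.  ``AND`` / ``OR`` / ``NOT`` and parentheses combine atoms; evaluation is
pure.

Quarterly series count, per calendar quarter of the admission's first note,
the admissions satisfying a criterion (numerator) over all admissions that
quarter (denominator).  The trend model is unweighted ordinary least squares
of the quarterly proportion on the quarter index — slope, two-sided 95% CI and
the p-value for slope = 0 are reported per quarter of elapsed time.  A
binomial-GLM alternative (slope on the logit scale) sits behind
``method="glm"``.

The Fisher exact test is computed by full hypergeometric enumeration in exact
rational arithmetic: two-sided p sums the probabilities of all tables with the
observed margins whose probability does not exceed the observed table's.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus_io import AdmissionDocument
from .exceptions import ConfigError
from .vectorize import normalize_text

# ---------------------------------------------------------------------------
# presence criteria
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lparen>\() | (?P<rparen>\)) |
        (?P<and>AND\b) | (?P<or>OR\b) | (?P<not>NOT\b) |
        (?P<word>word:"(?P<word_pat>[^"]+)") |
        (?P<code>code:"(?P<code_pat>[^"]+)") |
        (?P<stay>stay\s*(?P<stay_op>>=|<=|>|<|==)\s*(?P<stay_val>\d+(?:\.\d+)?))
    )""", re.VERBOSE)


@dataclass(frozen=True)
class AdmissionFacts:
    """Per-admission evidence a criterion is evaluated against."""
    tokens: frozenset
    codes: frozenset
    stay_days: float


class _Node:
    def evaluate(self, facts: AdmissionFacts) -> bool:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class _WordAtom(_Node):
    pattern: str

    def evaluate(self, facts: AdmissionFacts) -> bool:
        pat = self.pattern.lower()
        if pat.endswith("*"):
            stem = pat[:-1]
            return any(tok.startswith(stem) for tok in facts.tokens)
        return pat in facts.tokens


@dataclass(frozen=True)
class _CodeAtom(_Node):
    pattern: str

    def evaluate(self, facts: AdmissionFacts) -> bool:
        if self.pattern.endswith("*"):
            stem = self.pattern[:-1]
            return any(c.startswith(stem) for c in facts.codes)
        return self.pattern in facts.codes


@dataclass(frozen=True)
class _StayAtom(_Node):
    op: str
    value: float

    _OPS = {">=": lambda a, b: a >= b, "<=": lambda a, b: a <= b,
            ">": lambda a, b: a > b, "<": lambda a, b: a < b,
            "==": lambda a, b: a == b}

    def evaluate(self, facts: AdmissionFacts) -> bool:
        return self._OPS[self.op](facts.stay_days, self.value)


@dataclass(frozen=True)
class _Not(_Node):
    child: _Node

    def evaluate(self, facts: AdmissionFacts) -> bool:
        return not self.child.evaluate(facts)


@dataclass(frozen=True)
class _BinOp(_Node):
    op: str
    left: _Node
    right: _Node

    def evaluate(self, facts: AdmissionFacts) -> bool:
        if self.op == "AND":
            return self.left.evaluate(facts) and self.right.evaluate(facts)
        return self.left.evaluate(facts) or self.right.evaluate(facts)


class PresenceCriterion:
    """Parsed boolean criterion; ``evaluate`` is pure."""

    def __init__(self, expression: str, root: _Node):
        self.expression = expression
        self._root = root

    def __repr__(self) -> str:
        return f"PresenceCriterion({self.expression!r})"

    @classmethod
    def parse(cls, expression: str) -> "PresenceCriterion":
        tokens = cls._lex(expression)
        root, rest = cls._parse_or(tokens)
        if rest:
            raise ConfigError(f"criterion {expression!r}: trailing tokens {rest}")
        return cls(expression, root)

    @staticmethod
    def _lex(expression: str) -> List[Tuple[str, object]]:
        out: List[Tuple[str, object]] = []
        pos = 0
        while pos < len(expression):
            m = _TOKEN_RE.match(expression, pos)
            if not m:
                if expression[pos:].strip():
                    raise ConfigError(
                        f"criterion {expression!r}: cannot lex at {pos}: "
                        f"{expression[pos:pos + 15]!r}")
                break
            if m.lastgroup is None or m.end() == pos:
                break
            if m.group("word"):
                out.append(("atom", _WordAtom(m.group("word_pat"))))
            elif m.group("code"):
                out.append(("atom", _CodeAtom(m.group("code_pat"))))
            elif m.group("stay"):
                out.append(("atom", _StayAtom(m.group("stay_op"),
                                              float(m.group("stay_val")))))
            elif m.group("and"):
                out.append(("and", None))
            elif m.group("or"):
                out.append(("or", None))
            elif m.group("not"):
                out.append(("not", None))
            elif m.group("lparen"):
                out.append(("(", None))
            elif m.group("rparen"):
                out.append((")", None))
            pos = m.end()
        if not out:
            raise ConfigError(f"criterion {expression!r}: empty expression")
        return out

    @classmethod
    def _parse_or(cls, toks):
        node, toks = cls._parse_and(toks)
        while toks and toks[0][0] == "or":
            right, toks = cls._parse_and(toks[1:])
            node = _BinOp("OR", node, right)
        return node, toks

    @classmethod
    def _parse_and(cls, toks):
        node, toks = cls._parse_unary(toks)
        while toks and toks[0][0] == "and":
            right, toks = cls._parse_unary(toks[1:])
            node = _BinOp("AND", node, right)
        return node, toks

    @classmethod
    def _parse_unary(cls, toks):
        if not toks:
            raise ConfigError("criterion: unexpected end of expression")
        kind, val = toks[0]
        if kind == "not":
            child, rest = cls._parse_unary(toks[1:])
            return _Not(child), rest
        if kind == "(":
            node, rest = cls._parse_or(toks[1:])
            if not rest or rest[0][0] != ")":
                raise ConfigError("criterion: missing closing parenthesis")
            return node, rest[1:]
        if kind == "atom":
            return val, toks[1:]
        raise ConfigError(f"criterion: unexpected token {kind!r}")

    def evaluate(self, facts: AdmissionFacts) -> bool:
        return self._root.evaluate(facts)


def load_criteria(path: str) -> Dict[str, PresenceCriterion]:
    """Criteria file: one ``name: expression`` per line; '#' comments."""
    out: Dict[str, PresenceCriterion] = {}
    for line in open(path, encoding="utf-8"):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"criteria line needs 'name: expression': {line!r}")
        name, expr = line.split(":", 1)
        out[name.strip()] = PresenceCriterion.parse(expr.strip())
    return out


def admission_facts(doc: AdmissionDocument, codes: Optional[Sequence[str]] = None,
                    stay_days: float = 0.0, pii_mask: str = "") -> AdmissionFacts:
    """Build the evidence set for one admission (tokens after the vectorizer's
    normalization)."""
    tokens = frozenset(normalize_text(doc.text, pii_mask).split())
    return AdmissionFacts(tokens=tokens, codes=frozenset(codes or ()),
                          stay_days=stay_days)


# ---------------------------------------------------------------------------
# quarterly series and trend fit
# ---------------------------------------------------------------------------

@dataclass
class TrendSeries:
    """Per-quarter counts/proportions plus (after fitting) slope, CI, p."""

    quarters: List[str]                 # e.g. "2001Q3"
    numerators: np.ndarray
    denominators: np.ndarray
    criterion: str = ""
    slope: Optional[float] = None       # per quarter
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    method: str = ""

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.denominators > 0,
                            self.numerators / self.denominators, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quarter": self.quarters,
            "numerator": self.numerators,
            "denominator": self.denominators,
            "proportion": self.proportions,
        })


def make_quarters(start: str = "2001Q3", n_quarters: int = 28) -> List[pd.Period]:
    start_p = pd.Period(start, freq="Q")
    return [start_p + i for i in range(n_quarters)]


def quarterly_proportions(documents: Sequence[AdmissionDocument],
                          codes: Optional[pd.DataFrame],
                          criterion: PresenceCriterion,
                          quarters: Sequence[pd.Period],
                          pii_mask: str = "") -> TrendSeries:
    """Count admissions meeting the criterion per calendar quarter of their
    first note time; denominator is all admissions that quarter."""
    quarters = [pd.Period(q, freq="Q") for q in quarters]
    q_index = {q: i for i, q in enumerate(quarters)}
    code_map: Dict[str, Set[str]] = {}
    if codes is not None and len(codes):
        for adm, grp in codes.groupby("ADMISSION_ID"):
            code_map[adm] = set(grp["CODE"])
    num = np.zeros(len(quarters), dtype=int)
    den = np.zeros(len(quarters), dtype=int)
    for doc in documents:
        q = pd.Period(doc.first_charttime, freq="Q")
        if q not in q_index:
            raise ConfigError(
                f"admission {doc.admission_id} at {doc.first_charttime} is "
                f"outside the configured quarters {quarters[0]}..{quarters[-1]}")
        stay = 0.0  # single timestamp known per document; span needs raw notes
        facts = admission_facts(doc, code_map.get(doc.admission_id), stay,
                                pii_mask)
        i = q_index[q]
        den[i] += 1
        if criterion.evaluate(facts):
            num[i] += 1
    return TrendSeries(quarters=[str(q) for q in quarters], numerators=num,
                       denominators=den, criterion=criterion.expression)


def fit_trend(series: TrendSeries, method: str = "ols",
              alpha: float = 0.05) -> TrendSeries:
    """Fit proportion ~ quarter index; attach slope, two-sided CI, p-value.

    method="ols" (default): unweighted least squares on the quarterly
    proportions. method="glm": binomial GLM on the counts; the slope and CI
    are then on the logit scale.

    A perfect (zero-residual) fit has degenerate t statistics; it is mapped
    to CI width 0 with p = 1 for slope 0 and p = 0 otherwise.
    """
    y_all = series.proportions
    keep = ~np.isnan(y_all)
    x = np.flatnonzero(keep).astype(float)
    y = y_all[keep]
    if len(y) < 3:
        raise ConfigError("need at least 3 quarters with admissions to fit a trend")
    if np.ptp(x) == 0:
        raise ConfigError("zero variance in quarter index")
    X = sm.add_constant(x)
    if method == "ols":
        fit = sm.OLS(y, X).fit()
    elif method == "glm":
        n = series.numerators[keep]
        d = series.denominators[keep]
        fit = sm.GLM(np.column_stack([n, d - n]), X,
                     family=sm.families.Binomial()).fit()
    else:
        raise ConfigError(f"unknown trend method {method!r}")
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha)
    ci_low, ci_high = float(ci[1][0]), float(ci[1][1])
    p = float(fit.pvalues[1])
    # a zero-residual (perfect) fit has 0/0 t statistics; collapse it to the
    # boundary: CI width 0, p = 1 for slope 0 and p = 0 otherwise
    resid = np.asarray(y) - fit.predict(X)
    scale = max(1.0, float(np.abs(y).max()))
    if not math.isfinite(p) or float(np.abs(resid).max()) < 1e-12 * scale:
        p = 1.0 if abs(slope) < 1e-12 * scale else 0.0
        ci_low = ci_high = slope
        slope = 0.0 if p == 1.0 else slope
        ci_low = ci_high = slope
    return replace(series, slope=slope, ci_low=ci_low, ci_high=ci_high,
                   p_value=p, method=method)


def plot_trends(series_list: Sequence[TrendSeries], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for s in series_list:
        x = np.arange(len(s.quarters))
        label = s.criterion
        if s.slope is not None:
            label += (f" (slope={s.slope:.4g}, "
                      f"95% CI {s.ci_low:.4g} to {s.ci_high:.4g})")
        ax.plot(x, s.proportions, marker="o", ms=3, label=label)
    ax.set_xticks(np.arange(0, len(series_list[0].quarters), 4))
    ax.set_xticklabels(series_list[0].quarters[::4], rotation=45, ha="right")
    ax.set_ylabel("proportion of admissions")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact p by exact hypergeometric enumeration, plus the
    proportion difference a/(a+b) − c/(c+d).

    All four margins must be positive (an empty margin leaves nothing to
    compare).  Tables whose probability ties the observed probability are
    included in the two-sided sum (standard convention).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ConfigError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ConfigError("Fisher exact test needs all margins positive")
    n = r1 + r2

    denom = math.comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p = sum((q for k in range(lo, hi + 1) if (q := pmf(k)) <= p_obs),
            start=Fraction(0))
    diff = a / r1 - c / r2
    return min(float(p), 1.0), diff
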