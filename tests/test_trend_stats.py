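"""Presence criteria, quarterly series, trend fits, Fisher exact test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shakespeare as sk
from shakespeare.trend_stats import (AdmissionFacts, PresenceCriterion,
                                     TrendSeries, fisher_exact, fit_trend,
                                     make_quarters, quarterly_proportions)

from conftest import notes_to_records


def facts(tokens=(), codes=(), stay=0.0):
    return AdmissionFacts(frozenset(tokens), frozenset(codes), stay)


# --- criteria -----------------------------------------------------------------

@pytest.mark.parametrize("expr,f,expected", [
    ('word:"heparin"', facts({"heparin"}), True),
    ('word:"heparin"', facts({"heparinoid"}), False),
    ('word:"occlusion*"', facts({"occlusions"}), True),
    ('word:"occlusion*"', facts({"occl"}), False),
    ('code:"38.*"', facts(codes={"38.93"}), True),
    ('code:"38.*"', facts(codes={"338.9"}), False),
    ('stay>=14', facts(stay=20), True),
    ('stay>=14', facts(stay=3), False),
    ('word:"a" AND code:"x"', facts({"a"}, {"x"}), True),
    ('word:"a" AND code:"x"', facts({"a"}), False),
    ('word:"a" OR code:"x"', facts({"b"}, {"x"}), True),
    ('NOT word:"a"', facts({"b"}), True),
    ('word:"a" AND (code:"x" OR stay>=14)', facts({"a"}, stay=15), True),
])
def test_criterion_evaluation(expr, f, expected):
    assert PresenceCriterion.parse(expr).evaluate(f) is expected


def test_word_match_is_case_insensitive_whole_token():
    crit = PresenceCriterion.parse('word:"Heparin"')
    assert crit.evaluate(facts({"heparin"}))
    assert not crit.evaluate(facts({"heparin,"}))  # punctuation-bearing token
    assert PresenceCriterion.parse('word:"heparin*"').evaluate(
        facts({"heparin,"}))


@pytest.mark.parametrize("bad", ["", "word:", 'word:"a" AND', '(word:"a"',
                                 "bogus"])
def test_malformed_criteria_rejected(bad):
    with pytest.raises(sk.ConfigError):
        PresenceCriterion.parse(bad)


def test_criteria_file_loading(tmp_path):
    p = tmp_path / "criteria.txt"
    p.write_text("# comment\nheparin: word:\"heparin\"\n"
                 "combo: word:\"trauma\" AND code:\"99.04\"\n")
    crits = sk.load_criteria(p)
    assert set(crits) == {"heparin", "combo"}


# --- quarterly proportions ------------------------------------------------------

@pytest.fixture(scope="module")
def trend_world():
    config = sk.SynthConfig(n_admissions_per_group=150, n_under_16=0, seed=13)
    notes, codes, gt = sk.generate_cohort(config)
    records = notes_to_records(notes)
    docs = sk.assemble_documents(records, labels=gt.groups)
    return config, docs, codes, gt


def test_always_true_criterion_gives_proportion_one(trend_world):
    config, docs, codes, _ = trend_world
    crit = PresenceCriterion.parse('stay>=0')
    series = quarterly_proportions(docs, codes, crit,
                                   make_quarters("2001Q3", config.n_quarters))
    nonzero = series.denominators > 0
    assert np.all(series.proportions[nonzero] == 1.0)
    assert series.denominators.sum() == len(docs)


def test_quarterly_counts_match_brute_force_scan(trend_world):
    """Numerators/denominators equal a literal per-quarter scan for the
    injected trend term."""
    config, docs, codes, gt = trend_world
    token = config.trend_terms[0][0]
    crit = PresenceCriterion.parse(f'word:"{token}"')
    quarters = make_quarters("2001Q3", config.n_quarters)
    series = quarterly_proportions(docs, codes, crit, quarters,
                                   pii_mask=config.pii_mask_string)
    num = np.zeros(config.n_quarters, int)
    den = np.zeros(config.n_quarters, int)
    for d in docs:
        q = (pd.Period(d.first_charttime, freq="Q") - pd.Period("2001Q3")).n
        den[q] += 1
        if token in sk.normalize_text(d.text, config.pii_mask_string).split():
            num[q] += 1
    assert series.numerators.tolist() == num.tolist()
    assert series.denominators.tolist() == den.tolist()


def test_admission_outside_quarters_is_error(trend_world):
    _, docs, codes, _ = trend_world
    crit = PresenceCriterion.parse('stay>=0')
    with pytest.raises(sk.ConfigError):
        quarterly_proportions(docs, codes, crit, make_quarters("2001Q3", 2))


def test_code_criterion_counts_target_admissions(trend_world):
    _, docs, codes, gt = trend_world
    crit = PresenceCriterion.parse('code:"99.04"')
    series = quarterly_proportions(docs, codes, crit,
                                   make_quarters("2001Q3", 28))
    n_target = sum(1 for d in docs if gt.groups[d.admission_id] == "target")
    assert series.numerators.sum() == n_target


# --- trend fitting ---------------------------------------------------------------

def _series(nums, dens):
    nums = np.asarray(nums)
    dens = np.asarray(dens)
    return TrendSeries([f"Q{i}" for i in range(len(nums))], nums, dens)


def test_exact_line_recovers_slope_with_zero_width_ci():
    t = np.arange(10)
    s = fit_trend(_series((10 + 2 * t), np.full(10, 1000)))
    assert s.slope == pytest.approx(0.002, abs=1e-12)
    assert s.ci_high - s.ci_low == pytest.approx(0.0, abs=1e-12)


def test_constant_series_slope_zero_p_one():
    s = fit_trend(_series(np.full(6, 100), np.full(6, 1000)))
    assert s.slope == 0.0
    assert s.p_value == 1.0


def test_too_few_quarters_is_error():
    with pytest.raises(sk.ConfigError):
        fit_trend(_series([1, 2], [10, 10]))


def test_noisy_slope_recovered_within_ci():
    rng = np.random.default_rng(0)
    t = np.arange(28)
    nums = rng.binomial(500, 0.05 + 0.005 * t)
    s = fit_trend(_series(nums, np.full(28, 500)))
    assert s.ci_low <= 0.005 <= s.ci_high
    assert s.p_value < 0.001


def test_glm_variant_runs_and_agrees_in_sign():
    rng = np.random.default_rng(1)
    t = np.arange(28)
    nums = rng.binomial(500, 0.05 + 0.005 * t)
    s = fit_trend(_series(nums, np.full(28, 500)), method="glm")
    assert s.slope > 0 and s.method == "glm"


# --- Fisher exact -----------------------------------------------------------------

def test_symmetric_table():
    p, diff = fisher_exact([[5, 5], [5, 5]])
    assert p == 1.0 and diff == 0.0


def test_diagonal_table_enumeration():
    # margins (3,3,3,3): k in {0..3}, p(0)=p(3)=1/20, p(1)=p(2)=9/20;
    # observed a=3 -> two-sided p = 1/20 + 1/20 = 0.1
    p, diff = fisher_exact([[3, 0], [0, 3]])
    assert p == pytest.approx(0.1, abs=1e-15)
    assert diff == 1.0


def test_against_scipy_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        p, diff = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12)
        assert diff == pytest.approx(a / (a + b) - c / (c + d))


@pytest.mark.parametrize("table", [[[0, 0], [1, 1]], [[1, 0], [1, 0]]])
def test_empty_margin_is_error(table):
    with pytest.raises(sk.ConfigError):
        fisher_exact(table)


def test_negative_or_fractional_entries_rejected():
    with pytest.raises(sk.ConfigError):
        fisher_exact([[1, -1], [2, 2]])
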