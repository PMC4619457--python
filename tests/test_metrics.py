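"""Contingency table, predictive values, Wilson intervals, matched design."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adrproxy.adjudication import AscertainmentLevel as L
from adrproxy.adjudication import PatientClass as P
from adrproxy.episodes import PatternCategory as C
from adrproxy.errors import DataIntegrityError, InputError, UndefinedEstimateError
from adrproxy.metrics import (
    CONTINUATION_MINUS_DEATH,
    CONTINUATION_TOTAL,
    SWITCHERS_TOTAL,
    TOTAL_DISCONTINUATION,
    ValidationCounts,
    binomial_interval,
    match_controls,
    npv,
    ppv,
    sensitivity_specificity,
    tabulate,
    wilson_interval,
)

from oracles import wilson_bisect

approx = pytest.approx


# ---------------------------------------------------------------------------
# tabulation


def test_tabulate_hand_countable():
    patterns = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "category": [C.SWITCH_ARB, C.STOP, C.CONT_END_OF_STUDY],
        }
    )
    adjud = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "patient_class": [P.DEFINITE_ADR, P.NOTHING_MENTIONED, P.PROBABLE_ADR],
            "adr_term": ["cough", None, "bronchitis"],
        }
    )
    counts = tabulate(patterns, adjud)
    assert counts.total_n == 3
    assert counts.class_count(C.SWITCH_ARB, P.DEFINITE_ADR) == 1
    assert counts.definite_term_count(C.SWITCH_ARB, "cough") == 1
    assert counts.class_count(C.STOP, P.NOTHING_MENTIONED) == 1
    assert counts.class_count(C.CONT_END_OF_STUDY, P.PROBABLE_ADR) == 1


def test_tabulate_rejects_mismatched_patients():
    patterns = pd.DataFrame({"patient_id": ["a"], "category": [C.STOP]})
    adjud = pd.DataFrame(
        {"patient_id": ["b"], "patient_class": [P.NOTHING_MENTIONED], "adr_term": [None]}
    )
    with pytest.raises(DataIntegrityError):
        tabulate(patterns, adjud)


def test_tabulate_empty_cohort():
    empty_p = pd.DataFrame(columns=["patient_id", "category"])
    empty_a = pd.DataFrame(columns=["patient_id", "patient_class", "adr_term"])
    assert tabulate(empty_p, empty_a).total_n == 0


def test_published_table_margins_and_roundtrip(table2):
    assert table2.total_n == 1132
    assert table2.group_n(TOTAL_DISCONTINUATION) == 547  # 180 + 106 + 261
    assert table2.group_n(SWITCHERS_TOTAL) == 286
    assert table2.group_n(CONTINUATION_TOTAL) == 585
    assert table2.group_n(CONTINUATION_MINUS_DEATH) == 466
    assert table2.class_count(CONTINUATION_TOTAL, P.DEFINITE_ADR) == 28
    assert table2.class_count(CONTINUATION_TOTAL, P.PROBABLE_ADR) == 112
    rt = ValidationCounts.from_frame(table2.to_frame())
    assert rt.classes == table2.classes
    assert rt.definite_terms == {k: v for k, v in table2.definite_terms.items()}


def test_counts_reject_inconsistent_terms():
    classes = {C.SWITCH_ARB: {P.DEFINITE_ADR: 2}}
    with pytest.raises(InputError):
        ValidationCounts(classes=classes, definite_terms={C.SWITCH_ARB: {"cough": 5}})


# ---------------------------------------------------------------------------
# predictive values


def test_ppv_published_values(table2):
    assert ppv(table2, C.SWITCH_ARB, L.DEFINITE).estimate == approx(101 / 180)
    assert ppv(table2, C.SWITCH_ARB, L.AT_LEAST_PROBABLE).estimate == approx(123 / 180)
    assert ppv(table2, C.SWITCH_ARB, L.AT_LEAST_POSSIBLE).estimate == approx(163 / 180)
    assert ppv(table2, C.SWITCH_ARB, L.DEFINITE, term_filter="cough").estimate == approx(
        83 / 180
    )
    assert ppv(table2, TOTAL_DISCONTINUATION, L.DEFINITE).estimate == approx(194 / 547)


def test_ppv_zero_numerator_and_errors(table2):
    counts = ValidationCounts(classes={C.STOP: {P.NOTHING_MENTIONED: 10}})
    assert ppv(counts, C.STOP, L.DEFINITE).estimate == 0.0
    with pytest.raises(UndefinedEstimateError):
        ppv(counts, C.SWITCH_ARB, L.DEFINITE)  # empty group
    with pytest.raises(InputError):
        ppv(table2, C.CONT_DEATH, L.DEFINITE)  # not a test-positive group


def test_ppv_nested_across_levels(table2):
    for group in (C.SWITCH_ARB, C.SWITCH_OTHER, C.STOP, SWITCHERS_TOTAL, TOTAL_DISCONTINUATION):
        vals = [ppv(table2, group, lev).estimate for lev in L]
        assert vals == sorted(vals)


def test_npv_published_values(table2):
    assert npv(table2, CONTINUATION_TOTAL, L.AT_LEAST_POSSIBLE).estimate == approx(
        (585 - 28) / 585
    )
    assert npv(table2, CONTINUATION_TOTAL, L.AT_LEAST_PROBABLE).estimate == approx(
        (585 - 28 - 112) / 585
    )


def test_npv_edge_cases(table2):
    with pytest.raises(UndefinedEstimateError):
        npv(table2, CONTINUATION_TOTAL, L.DEFINITE)
    with pytest.raises(InputError):
        npv(table2, C.STOP, L.AT_LEAST_POSSIBLE)
    clean = ValidationCounts(classes={C.CONT_DEATH: {P.NOTHING_MENTIONED: 12}})
    assert npv(clean, C.CONT_DEATH, L.AT_LEAST_PROBABLE).estimate == 1.0


# ---------------------------------------------------------------------------
# confidence intervals


def test_wilson_reproduces_published_interval():
    lo, hi = wilson_interval(101, 180)
    assert lo == approx(0.4881, abs=1e-4)
    assert hi == approx(0.6316, abs=1e-4)


def test_wilson_boundaries():
    assert wilson_interval(0, 50)[0] == 0.0
    assert wilson_interval(50, 50)[1] == 1.0


@pytest.mark.parametrize("k,n", [(1, 10), (5, 10), (101, 180), (42, 106), (0, 7), (7, 7), (250, 1000)])
@pytest.mark.parametrize("conf", [0.90, 0.95, 0.99])
def test_wilson_equals_score_equation_roots(k, n, conf):
    lo, hi = wilson_interval(k, n, conf)
    blo, bhi = wilson_bisect(k, n, conf)
    assert lo == approx(blo, abs=1e-9)
    assert hi == approx(bhi, abs=1e-9)


def test_interval_properties():
    # contains the point estimate; width shrinks with n at fixed proportion
    for k, n in [(3, 9), (30, 90), (300, 900)]:
        lo, hi = wilson_interval(k, n)
        assert lo <= k / n <= hi
    widths = [np.diff(wilson_interval(k, n))[0] for k, n in [(3, 9), (30, 90), (300, 900)]]
    assert widths[0] > widths[1] > widths[2]


def test_alternative_ci_methods():
    for method in ("clopper-pearson", "wald"):
        lo, hi = binomial_interval(101, 180, method=method)
        assert 0.0 <= lo < 101 / 180 < hi <= 1.0
    with pytest.raises(InputError):
        binomial_interval(5, 4)
    with pytest.raises(InputError):
        binomial_interval(1, 10, method="bayes")


# ---------------------------------------------------------------------------
# matched-control design


def test_match_controls_only_eligible():
    pairs, unmatched = match_controls([("case", 300)], [("short", 250), ("long", 400)], 1)
    assert unmatched == []
    assert pairs[0].control_id == "long"
    assert pairs[0].evaluation_duration_days == 300


def test_match_controls_exhaustion():
    pairs, unmatched = match_controls(
        [("c1", 300), ("c2", 350)], [("only", 400)], 1
    )
    assert len(pairs) == 1 and len(unmatched) == 1
    assert pairs[0].case_id == "c2"  # longer case is matched first
    assert unmatched == ["c1"]


def test_match_controls_deterministic_and_valid():
    rng = np.random.default_rng(42)
    cases = [(f"case{i}", int(rng.integers(30, 900))) for i in range(60)]
    pool = [(f"ctrl{i}", int(rng.integers(30, 1200))) for i in range(80)]
    a, ua = match_controls(cases, pool, 7)
    b, ub = match_controls(cases, pool, 7)
    assert a == b and ua == ub
    durations = dict(pool)
    used = [p.control_id for p in a]
    assert len(used) == len(set(used)), "controls must not be reused"
    for p in a:
        assert durations[p.control_id] >= p.evaluation_duration_days


# ---------------------------------------------------------------------------
# sensitivity / specificity


def test_sensitivity_specificity_counts():
    # 101 definite among 180 cases, 9 definite among 180 matched controls
    cases = [P.DEFINITE_ADR] * 101 + [P.NOTHING_MENTIONED] * 79
    controls = [P.DEFINITE_ADR] * 9 + [P.NOTHING_MENTIONED] * 171
    sens, spec = sensitivity_specificity(cases, controls)
    assert sens.numerator == 101 and sens.denominator == 110
    assert sens.estimate == approx(101 / 110)
    assert spec.numerator == 171 and spec.denominator == 250
    assert spec.estimate == approx(171 / 250)


def test_sensitivity_specificity_edges():
    sens, _ = sensitivity_specificity([P.DEFINITE_ADR], [P.NOTHING_MENTIONED])
    assert sens.estimate == 1.0  # no definite ADR among controls
    with pytest.raises(UndefinedEstimateError):
        sensitivity_specificity([], [])
    with pytest.raises(InputError):
        sensitivity_specificity([P.DEFINITE_ADR], [P.NOTHING_MENTIONED] * 2)
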