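"""Accuracy metrics for prescription-pattern proxies.

The central object is the :class:`ValidationCounts` contingency table:
pattern category x adjudication class, with the reaction-term breakdown of
the definite ADRs kept alongside so the cough-specific predictive value can
be computed.  Positive predictive values are computed for the test-positive
categories (and their margins) at the three nested ascertainment levels;
negative predictive values for the continuation subgroups; sensitivity and
specificity from duration-matched case/control pairs, counting definite ADRs
only.  All proportions carry two-sided Wilson score intervals by default
(Clopper-Pearson and Wald are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .adjudication import AscertainmentLevel, LEVEL_CLASSES, PatientClass, in_level
from .episodes import PatternCategory
from .errors import DataIntegrityError, InputError, UndefinedEstimateError

__all__ = [
    "ValidationCounts",
    "AccuracyEstimate",
    "MatchedPair",
    "Group",
    "SWITCHERS_TOTAL",
    "TOTAL_DISCONTINUATION",
    "CONTINUATION_TOTAL",
    "CONTINUATION_MINUS_DEATH",
    "tabulate",
    "ppv",
    "npv",
    "wilson_interval",
    "binomial_interval",
    "match_controls",
    "sensitivity_specificity",
]

# Margin identifiers accepted wherever a group/subgroup is expected.
SWITCHERS_TOTAL = "SWITCHERS_TOTAL"
TOTAL_DISCONTINUATION = "TOTAL_DISCONTINUATION"
CONTINUATION_TOTAL = "CONTINUATION_TOTAL"
CONTINUATION_MINUS_DEATH = "CONTINUATION_MINUS_DEATH"

Group = PatternCategory | str

_MARGIN_MEMBERS: dict[str, tuple[PatternCategory, ...]] = {
    SWITCHERS_TOTAL: (PatternCategory.SWITCH_ARB, PatternCategory.SWITCH_OTHER),
    TOTAL_DISCONTINUATION: (
        PatternCategory.SWITCH_ARB,
        PatternCategory.SWITCH_OTHER,
        PatternCategory.STOP,
    ),
    CONTINUATION_TOTAL: (
        PatternCategory.CONT_END_OF_STUDY,
        PatternCategory.CONT_OUT_OF_STUDY,
        PatternCategory.CONT_DEATH,
    ),
    CONTINUATION_MINUS_DEATH: (
        PatternCategory.CONT_END_OF_STUDY,
        PatternCategory.CONT_OUT_OF_STUDY,
    ),
}

_TEST_POSITIVE_GROUPS = {SWITCHERS_TOTAL, TOTAL_DISCONTINUATION}
_CONTINUATION_GROUPS = {CONTINUATION_TOTAL, CONTINUATION_MINUS_DEATH}


def resolve_group(group: Group) -> tuple[PatternCategory, ...]:
    """Expand a category or margin identifier into its member categories."""
    if isinstance(group, PatternCategory):
        return (group,)
    key = str(group).upper()
    if key in _MARGIN_MEMBERS:
        return _MARGIN_MEMBERS[key]
    try:
        return (PatternCategory(key),)
    except ValueError:
        raise InputError(f"unknown group {group!r}") from None


@dataclass
class ValidationCounts:
    """Pattern category x adjudication class counts with definite-ADR terms.

    ``classes[cat][cls]`` is the number of patients in pattern category
    ``cat`` whose adjudicated class is ``cls``; ``definite_terms[cat][term]``
    breaks the definite ADRs down by reaction term.
    """

    classes: dict[PatternCategory, dict[PatientClass, int]]
    definite_terms: dict[PatternCategory, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in PatternCategory:
            cell = self.classes.setdefault(cat, {})
            for cls in PatientClass:
                cell.setdefault(cls, 0)
            self.definite_terms.setdefault(cat, {})
        for cat, terms in self.definite_terms.items():
            total = sum(terms.values())
            if terms and total != self.classes[cat][PatientClass.DEFINITE_ADR]:
                raise InputError(
                    f"definite-ADR term counts for {cat.value} sum to {total}, "
                    f"expected {self.classes[cat][PatientClass.DEFINITE_ADR]}"
                )

    # -- margins -----------------------------------------------------------
    def group_n(self, group: Group) -> int:
        return sum(
            sum(self.classes[cat].values()) for cat in resolve_group(group)
        )

    def class_count(self, group: Group, cls: PatientClass) -> int:
        return sum(self.classes[cat][cls] for cat in resolve_group(group))

    def level_count(self, group: Group, level: AscertainmentLevel) -> int:
        return sum(
            self.class_count(group, cls) for cls in LEVEL_CLASSES[AscertainmentLevel(level)]
        )

    def definite_term_count(self, group: Group, term: str) -> int:
        return sum(
            self.definite_terms.get(cat, {}).get(term, 0)
            for cat in resolve_group(group)
        )

    @property
    def total_n(self) -> int:
        return sum(self.group_n(cat) for cat in PatternCategory)

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per category; class columns plus ``term_<name>`` columns."""
        terms = sorted({t for d in self.definite_terms.values() for t in d})
        rows = []
        for cat in PatternCategory:
            row: dict[str, object] = {"category": cat.value, "n": self.group_n(cat)}
            for cls in PatientClass:
                row[cls.value.lower()] = self.classes[cat][cls]
            for t in terms:
                row[f"term_{t}"] = self.definite_terms[cat].get(t, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ValidationCounts":
        classes: dict[PatternCategory, dict[PatientClass, int]] = {}
        terms: dict[PatternCategory, dict[str, int]] = {}
        term_cols = [c for c in df.columns if c.startswith("term_")]
        for r in df.to_dict("records"):
            cat = PatternCategory(str(r["category"]).upper())
            classes[cat] = {
                c: int(r.get(c.value.lower(), 0) or 0) for c in PatientClass
            }
            terms[cat] = {
                c[len("term_"):]: int(r.get(c, 0) or 0)
                for c in term_cols
                if int(r.get(c, 0) or 0)
            }
        return cls(classes=classes, definite_terms=terms)


@dataclass(frozen=True)
class AccuracyEstimate:
    """A proportion with its counts and a two-sided confidence interval."""

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = "wilson"

    @property
    def pct(self) -> float:
        return 100.0 * self.estimate

    def __str__(self) -> str:  # e.g. "56.1 % (48.8-63.2)"
        return (
            f"{self.pct:.1f} % ({100 * self.ci_low:.1f}-{100 * self.ci_high:.1f})"
        )


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    evaluation_duration_days: int


def binomial_interval(
    numerator: int,
    denominator: int,
    conf_level: float = 0.95,
    method: str = "wilson",
) -> tuple[float, float]:
    """Two-sided binomial CI; ``method`` in {wilson, clopper-pearson, wald}."""
    if denominator <= 0 or not 0 <= numerator <= denominator:
        raise InputError(
            f"invalid counts for a proportion: {numerator}/{denominator}"
        )
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta", "wald": "normal"}.get(
        method
    )
    if sm_method is None:
        raise InputError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(numerator, denominator, 1 - conf_level, sm_method)
    # the exact score/beta bounds at the boundaries are 0 and 1
    lo = 0.0 if numerator == 0 else max(0.0, float(lo))
    hi = 1.0 if numerator == denominator else min(1.0, float(hi))
    return lo, hi


def wilson_interval(
    numerator: int, denominator: int, conf_level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval (inverts the score test; stable near 0 and 1)."""
    return binomial_interval(numerator, denominator, conf_level, "wilson")


def make_estimate(
    numerator: int,
    denominator: int,
    conf_level: float = 0.95,
    method: str = "wilson",
) -> AccuracyEstimate:
    if denominator == 0:
        raise UndefinedEstimateError("proportion undefined for zero denominator")
    lo, hi = binomial_interval(numerator, denominator, conf_level, method)
    return AccuracyEstimate(
        numerator, denominator, numerator / denominator, lo, hi, conf_level, method
    )


def tabulate(
    pattern_results: pd.DataFrame, adjudication_results: pd.DataFrame
) -> ValidationCounts:
    """Cross-tabulate pattern categories against adjudicated classes.

    Both frames must cover exactly the same patients (one row each).
    """
    p = pattern_results[["patient_id", "category"]].copy()
    a = adjudication_results[["patient_id", "patient_class", "adr_term"]].copy()
    p["patient_id"] = p["patient_id"].astype(str)
    a["patient_id"] = a["patient_id"].astype(str)
    only_p = set(p["patient_id"]) - set(a["patient_id"])
    only_a = set(a["patient_id"]) - set(p["patient_id"])
    if only_p or only_a:
        raise DataIntegrityError(
            "pattern and adjudication results cover different patients "
            f"(e.g. {sorted(only_p | only_a)[:5]})"
        )
    if p["patient_id"].duplicated().any() or a["patient_id"].duplicated().any():
        raise DataIntegrityError("duplicate patient in results")
    merged = p.merge(a, on="patient_id")
    classes: dict[PatternCategory, dict[PatientClass, int]] = {
        cat: {cls: 0 for cls in PatientClass} for cat in PatternCategory
    }
    terms: dict[PatternCategory, dict[str, int]] = {cat: {} for cat in PatternCategory}
    for r in merged.itertuples():
        cat = PatternCategory(r.category)
        cls = PatientClass(r.patient_class)
        classes[cat][cls] += 1
        if cls is PatientClass.DEFINITE_ADR:
            term = r.adr_term if isinstance(r.adr_term, str) and r.adr_term else "unspecified"
            terms[cat][term] = terms[cat].get(term, 0) + 1
    return ValidationCounts(classes=classes, definite_terms=terms)


def ppv(
    counts: ValidationCounts,
    group: Group,
    level: AscertainmentLevel,
    term_filter: str | None = None,
    conf_level: float = 0.95,
    method: str = "wilson",
) -> AccuracyEstimate:
    """Positive predictive value of a test-positive pattern group.

    The numerator counts patients whose adjudicated class belongs to the
    ascertainment level; with ``term_filter`` it counts definite ADRs with
    that reaction term only (the cough-specific variant).  The denominator is
    the group size.
    """
    cats = resolve_group(group)
    if any(c.is_continuation for c in cats):
        raise InputError(f"PPV is defined for test-positive groups, got {group!r}")
    denom = counts.group_n(group)
    if denom == 0:
        raise UndefinedEstimateError(f"group {group!r} is empty")
    if term_filter is not None:
        num = counts.definite_term_count(group, term_filter)
    else:
        num = counts.level_count(group, level)
    return make_estimate(num, denom, conf_level, method)


def npv(
    counts: ValidationCounts,
    continuation_subgroup: Group,
    level: AscertainmentLevel,
    conf_level: float = 0.95,
    method: str = "wilson",
) -> AccuracyEstimate:
    """Negative predictive value of a continuation subgroup.

    At the at-least-possible level only the definite ADRs are deducted from
    the subgroup; at the at-least-probable level definite and probable ADRs
    are deducted.  A definite-only NPV is not defined.
    """
    level = AscertainmentLevel(level)
    if level is AscertainmentLevel.DEFINITE:
        raise UndefinedEstimateError("NPV is not defined at the DEFINITE level")
    cats = resolve_group(continuation_subgroup)
    if any(not c.is_continuation for c in cats):
        raise InputError(
            f"NPV is defined for continuation subgroups, got {continuation_subgroup!r}"
        )
    denom = counts.group_n(continuation_subgroup)
    if denom == 0:
        raise UndefinedEstimateError(f"subgroup {continuation_subgroup!r} is empty")
    deduct = counts.class_count(continuation_subgroup, PatientClass.DEFINITE_ADR)
    if level is AscertainmentLevel.AT_LEAST_PROBABLE:
        deduct += counts.class_count(continuation_subgroup, PatientClass.PROBABLE_ADR)
    return make_estimate(denom - deduct, denom, conf_level, method)


def match_controls(
    cases: Iterable[tuple[str, int]],
    continuers: Iterable[tuple[str, int]],
    rng: np.random.Generator | int | None = None,
) -> tuple[list[MatchedPair], list[str]]:
    """Match each test-positive case to an unused continuer with at least the
    case's ACEI duration.

    Cases are processed in descending duration order (ties broken by id) and
    matched uniformly at random among eligible continuers, without
    replacement.  Returns ``(pairs, unmatched_case_ids)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    case_list = sorted(cases, key=lambda c: (-int(c[1]), str(c[0])))
    pool = sorted(continuers, key=lambda c: (-int(c[1]), str(c[0])))
    eligible: list[str] = []  # ids of unused continuers with duration >= current case
    ptr = 0
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for cid, cdur in case_list:
        while ptr < len(pool) and int(pool[ptr][1]) >= int(cdur):
            eligible.append(str(pool[ptr][0]))
            ptr += 1
        if not eligible:
            unmatched.append(str(cid))
            continue
        k = int(rng.integers(len(eligible)))
        control = eligible[k]
        eligible[k] = eligible[-1]
        eligible.pop()
        pairs.append(MatchedPair(str(cid), control, int(cdur)))
    return pairs, unmatched


def sensitivity_specificity(
    case_classes: Sequence[PatientClass],
    control_classes: Sequence[PatientClass],
    conf_level: float = 0.95,
    method: str = "wilson",
) -> tuple[AccuracyEstimate, AccuracyEstimate]:
    """Sensitivity and specificity of the proxy, definite ADRs only.

    Cases (test positive) with a definite ADR are true positives; matched
    controls (test negative) with a definite ADR are false negatives.
    """
    if len(case_classes) == 0 or len(control_classes) == 0:
        raise UndefinedEstimateError("empty matched sets")
    if len(case_classes) != len(control_classes):
        raise InputError("matched case and control sets must have equal size")
    tp = sum(PatientClass(c) is PatientClass.DEFINITE_ADR for c in case_classes)
    fp = len(case_classes) - tp
    fn = sum(PatientClass(c) is PatientClass.DEFINITE_ADR for c in control_classes)
    tn = len(control_classes) - fn
    sens = make_estimate(tp, tp + fn, conf_level, method)
    spec = make_estimate(tn, tn + fp, conf_level, method)
    return sens, spec
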