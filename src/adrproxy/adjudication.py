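"""Patient-level adjudication of coded medical-record events.

The general-practitioner chart review is represented by coded events: each
event carries an adjudication code (definite ADR, definite non-ADR, probable
ADR, or a non-probable health problem) and, for the ADR codes, the reaction
term (cough, angioedema, ...).  A patient's class over a review window is the
highest-precedence code among the events falling in it; a patient with no
event in the window is NOTHING_MENTIONED — an ADR is then still *possible*,
which is why the widest ascertainment level includes this class.

Windows are closed on both ends.  Test-positive patients (switch/stop) are
reviewed from 180 days before to 90 days after the index date.  Matched
controls are reviewed from their ACEI start for the matched case's ACEI
duration.  Continuers outside the matched subsample are reviewed over their
whole ACEI episode.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .errors import DataIntegrityError, InputError

__all__ = [
    "AdjudicationCode",
    "PatientClass",
    "AscertainmentLevel",
    "LEVEL_CLASSES",
    "GPEvent",
    "AdjudicationResult",
    "adjudicate_case",
    "adjudicate_control",
    "adjudicate_window",
    "adjudicate_cohort",
    "in_level",
]

DEFAULT_BEFORE_DAYS = 180
DEFAULT_AFTER_DAYS = 90


class AdjudicationCode(str, Enum):
    """Code attached to a single medical-record event."""

    DEFINITE_ADR = "DEFINITE_ADR"
    DEFINITE_NON_ADR = "DEFINITE_NON_ADR"
    PROBABLE_ADR = "PROBABLE_ADR"
    NON_PROBABLE_HP = "NON_PROBABLE_HP"


class PatientClass(str, Enum):
    """Patient-level class over a review window (event codes + empty case)."""

    DEFINITE_ADR = "DEFINITE_ADR"
    DEFINITE_NON_ADR = "DEFINITE_NON_ADR"
    PROBABLE_ADR = "PROBABLE_ADR"
    NON_PROBABLE_HP = "NON_PROBABLE_HP"
    NOTHING_MENTIONED = "NOTHING_MENTIONED"


#: A confirmed ADR dominates everything; an explicit physician reason for the
#: change dominates speculative mentions.
PRECEDENCE: tuple[AdjudicationCode, ...] = (
    AdjudicationCode.DEFINITE_ADR,
    AdjudicationCode.DEFINITE_NON_ADR,
    AdjudicationCode.PROBABLE_ADR,
    AdjudicationCode.NON_PROBABLE_HP,
)

_TERM_CODES = {AdjudicationCode.DEFINITE_ADR, AdjudicationCode.PROBABLE_ADR}


class AscertainmentLevel(str, Enum):
    """Nested numerator definitions for the accuracy metrics."""

    DEFINITE = "DEFINITE"
    AT_LEAST_PROBABLE = "AT_LEAST_PROBABLE"
    AT_LEAST_POSSIBLE = "AT_LEAST_POSSIBLE"


LEVEL_CLASSES: dict[AscertainmentLevel, frozenset[PatientClass]] = {
    AscertainmentLevel.DEFINITE: frozenset({PatientClass.DEFINITE_ADR}),
    AscertainmentLevel.AT_LEAST_PROBABLE: frozenset(
        {PatientClass.DEFINITE_ADR, PatientClass.PROBABLE_ADR}
    ),
    AscertainmentLevel.AT_LEAST_POSSIBLE: frozenset(
        {
            PatientClass.DEFINITE_ADR,
            PatientClass.PROBABLE_ADR,
            PatientClass.NOTHING_MENTIONED,
        }
    ),
}


@dataclass(frozen=True)
class GPEvent:
    patient_id: str
    event_date: _dt.date
    adjudication_code: AdjudicationCode
    adr_term: str | None = None

    def __post_init__(self) -> None:
        if self.adr_term is not None and self.adjudication_code not in _TERM_CODES:
            raise InputError(
                "adr_term only applies to DEFINITE_ADR / PROBABLE_ADR events"
            )


@dataclass(frozen=True)
class AdjudicationResult:
    patient_id: str
    patient_class: PatientClass
    adr_term: str | None
    window_start: _dt.date
    window_end: _dt.date


def in_level(patient_class: PatientClass, level: AscertainmentLevel) -> bool:
    """Whether a patient class counts toward an ascertainment level.

    DEFINITE_NON_ADR and NON_PROBABLE_HP belong to no level; the empty
    NOTHING_MENTIONED class belongs only to AT_LEAST_POSSIBLE.
    """
    return PatientClass(patient_class) in LEVEL_CLASSES[AscertainmentLevel(level)]


def adjudicate_window(
    patient_id: str,
    events: Iterable[GPEvent],
    window_start: _dt.date,
    window_end: _dt.date,
) -> AdjudicationResult:
    """Classify a patient from the events in a closed date window.

    The class is the highest-precedence code present; ties within a code are
    broken by event date (earliest wins) so the result is independent of the
    input order.  The supporting reaction term is carried for ADR classes.
    """
    candidates = [
        e
        for e in events
        if e.patient_id == patient_id and window_start <= e.event_date <= window_end
    ]
    for code in PRECEDENCE:
        hits = sorted(
            (e for e in candidates if e.adjudication_code == code),
            key=lambda e: (e.event_date, e.adr_term or ""),
        )
        if hits:
            cls = PatientClass(code.value)
            term = hits[0].adr_term if code in _TERM_CODES else None
            return AdjudicationResult(patient_id, cls, term, window_start, window_end)
    return AdjudicationResult(
        patient_id, PatientClass.NOTHING_MENTIONED, None, window_start, window_end
    )


def adjudicate_case(
    patient_id: str,
    events: Iterable[GPEvent],
    index_date: _dt.date,
    before_days: int = DEFAULT_BEFORE_DAYS,
    after_days: int = DEFAULT_AFTER_DAYS,
) -> AdjudicationResult:
    """Adjudicate a test-positive patient around the switch/stop index date."""
    if before_days < 0 or after_days < 0:
        raise InputError("window extents must be non-negative")
    return adjudicate_window(
        patient_id,
        events,
        index_date - _dt.timedelta(days=before_days),
        index_date + _dt.timedelta(days=after_days),
    )


def adjudicate_control(
    patient_id: str,
    events: Iterable[GPEvent],
    acei_start_date: _dt.date,
    duration_days: int,
) -> AdjudicationResult:
    """Adjudicate a matched control from ACEI start over the case's duration."""
    if duration_days < 0:
        raise InputError("duration_days must be >= 0")
    return adjudicate_window(
        patient_id,
        events,
        acei_start_date,
        acei_start_date + _dt.timedelta(days=duration_days),
    )


def _events_from_frame(events: pd.DataFrame) -> dict[str, list[GPEvent]]:
    out: dict[str, list[GPEvent]] = {}
    for r in events.itertuples():
        term = getattr(r, "adr_term", None)
        if term is not None and (pd.isna(term) or term == ""):
            term = None
        ev = GPEvent(
            str(r.patient_id),
            pd.Timestamp(r.event_date).date(),
            AdjudicationCode(r.adjudication_code),
            term,
        )
        out.setdefault(ev.patient_id, []).append(ev)
    return out


def adjudicate_cohort(
    pattern_results: pd.DataFrame,
    events: pd.DataFrame,
    before_days: int = DEFAULT_BEFORE_DAYS,
    after_days: int = DEFAULT_AFTER_DAYS,
) -> pd.DataFrame:
    """Adjudicate every classified patient.

    Test-positive patients are reviewed in the closed window
    ``[index - before_days, index + after_days]``; continuers over their
    whole ACEI episode ``[episode_start, episode_start + acei_duration_days]``
    (the episode end truncated at exit).  Returns a frame with columns
    ``patient_id, patient_class, adr_term, window_start, window_end``.

    Raises :class:`DataIntegrityError` if an event references a patient not
    present in ``pattern_results``.
    """
    by_patient = _events_from_frame(events)
    known = set(pattern_results["patient_id"].astype(str))
    orphans = set(by_patient) - known
    if orphans:
        raise DataIntegrityError(
            f"GP events for patients outside the cohort: {sorted(orphans)[:5]}"
        )
    rows = []
    for r in pattern_results.itertuples():
        pid = str(r.patient_id)
        evs = by_patient.get(pid, [])
        if r.index_date is not None and not pd.isna(r.index_date):
            res = adjudicate_case(
                pid, evs, pd.Timestamp(r.index_date).date(), before_days, after_days
            )
        else:
            start = pd.Timestamp(r.episode_start).date()
            res = adjudicate_control(pid, evs, start, int(r.acei_duration_days))
        rows.append(
            (pid, res.patient_class, res.adr_term, res.window_start, res.window_end)
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "patient_class", "adr_term", "window_start", "window_end"],
    )
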