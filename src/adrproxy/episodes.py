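"""Treatment-episode construction and prescription-pattern classification.

Dispensing records carry an ATC code, a dispense date, the number of units
dispensed and the prescribed daily number.  The *theoretical end date* of a
prescription is the dispense date plus units/daily_number days: the first day
the supply has run out.  An ACE-inhibitor (ACEI) *treatment episode* chains
prescriptions as long as each renewal occurs within ``gap_days`` of the
running theoretical end of the episode; the episode end is the running
maximum of chained end dates, so stockpiled (overlapping) prescriptions
extend coverage but are not appended end-to-end.

Every new user is then classified into one of six mutually exclusive
prescription-pattern categories.  Patients whose follow-up ends within
``gap_days`` of the episode end are continuers, subdivided by the reason
follow-up ended (end of study / moved out of the catchment area / death).
All others discontinued: the episode end becomes the *index date*, and the
dispensings in the ``switch_window_days`` after it decide between switching
to an angiotensin receptor blocker (ARB), switching to another
antihypertensive, or stopping.  ARB takes precedence over the other
antihypertensive classes, mirroring the guideline replacement for
ACEI-induced adverse reactions.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InputError

__all__ = [
    "DrugClass",
    "ExitReason",
    "PatternCategory",
    "DispensingRecord",
    "FollowUpRecord",
    "TreatmentEpisode",
    "PatternResult",
    "DEFAULT_CLASS_MAP",
    "classify_atc",
    "prescription_end",
    "prescription_duration_days",
    "identify_starters",
    "build_treatment_episode",
    "classify_pattern",
    "classify_cohort",
    "reclassification_delta",
]

DEFAULT_STUDY_START = _dt.date(2000, 1, 1)
DEFAULT_STUDY_END = _dt.date(2011, 1, 1)
DEFAULT_LOOKBACK_DAYS = 182


class DrugClass(str, Enum):
    """Antihypertensive drug classes relevant to the switch scan."""

    ACEI = "ACEI"
    ARB = "ARB"
    BETA_BLOCKER = "BETA_BLOCKER"
    CCB = "CCB"
    DIURETIC = "DIURETIC"
    OTHER_ANTIHYPERTENSIVE = "OTHER_ANTIHYPERTENSIVE"


#: Classes that count as "another antihypertensive" in the switch scan.
NON_ARB_ALTERNATIVES = frozenset(
    {
        DrugClass.BETA_BLOCKER,
        DrugClass.CCB,
        DrugClass.DIURETIC,
        DrugClass.OTHER_ANTIHYPERTENSIVE,
    }
)


class ExitReason(str, Enum):
    END_OF_STUDY = "END_OF_STUDY"
    MOVED_OUT = "MOVED_OUT"
    DEATH = "DEATH"


class PatternCategory(str, Enum):
    """Mutually exclusive prescription-pattern categories."""

    CONT_END_OF_STUDY = "CONT_END_OF_STUDY"
    CONT_OUT_OF_STUDY = "CONT_OUT_OF_STUDY"
    CONT_DEATH = "CONT_DEATH"
    STOP = "STOP"
    SWITCH_ARB = "SWITCH_ARB"
    SWITCH_OTHER = "SWITCH_OTHER"

    @property
    def is_continuation(self) -> bool:
        return self in _CONTINUATION

    @property
    def is_test_positive(self) -> bool:
        return not self.is_continuation


_CONTINUATION = frozenset(
    {
        PatternCategory.CONT_END_OF_STUDY,
        PatternCategory.CONT_OUT_OF_STUDY,
        PatternCategory.CONT_DEATH,
    }
)

_EXIT_TO_CATEGORY = {
    ExitReason.END_OF_STUDY: PatternCategory.CONT_END_OF_STUDY,
    ExitReason.MOVED_OUT: PatternCategory.CONT_OUT_OF_STUDY,
    ExitReason.DEATH: PatternCategory.CONT_DEATH,
}

#: ATC prefix -> drug class, longest-prefix-first lookup.  C09A/C09B are ACEI
#: mono- and combination products; C09C/C09D the ARB analogues.
DEFAULT_CLASS_MAP: tuple[tuple[str, DrugClass], ...] = (
    ("C09A", DrugClass.ACEI),
    ("C09B", DrugClass.ACEI),
    ("C09C", DrugClass.ARB),
    ("C09D", DrugClass.ARB),
    ("C07", DrugClass.BETA_BLOCKER),
    ("C08", DrugClass.CCB),
    ("C03", DrugClass.DIURETIC),
    ("C02", DrugClass.OTHER_ANTIHYPERTENSIVE),
)


@dataclass(frozen=True)
class DispensingRecord:
    patient_id: str
    atc_code: str
    dispense_date: _dt.date
    units_dispensed: float
    daily_number: float

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise InputError("atc_code must be non-empty")
        if self.units_dispensed <= 0:
            raise InputError(f"units_dispensed must be > 0, got {self.units_dispensed}")
        if self.daily_number <= 0:
            raise InputError(f"daily_number must be > 0, got {self.daily_number}")


@dataclass(frozen=True)
class FollowUpRecord:
    patient_id: str
    entry_date: _dt.date
    exit_date: _dt.date
    exit_reason: ExitReason

    def __post_init__(self) -> None:
        if self.entry_date >= self.exit_date:
            raise InputError(
                f"entry_date {self.entry_date} must precede exit_date {self.exit_date}"
            )


@dataclass(frozen=True)
class TreatmentEpisode:
    patient_id: str
    start_date: _dt.date
    episode_end: _dt.date
    n_prescriptions: int
    duration_days: int


@dataclass(frozen=True)
class PatternResult:
    patient_id: str
    category: PatternCategory
    index_date: _dt.date | None
    acei_duration_days: int
    gap_days: int
    episode_start: _dt.date = field(default=None)  # type: ignore[assignment]
    episode_end: _dt.date = field(default=None)  # type: ignore[assignment]


def _validated_map(
    class_map: Sequence[tuple[str, DrugClass]] | None,
) -> tuple[tuple[str, DrugClass], ...]:
    if class_map is None:
        return DEFAULT_CLASS_MAP
    entries = tuple((str(p), DrugClass(c)) for p, c in class_map)
    for i, (a, _) in enumerate(entries):
        if not a:
            raise InputError("empty ATC prefix in class map")
        for b, _ in entries[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise InputError(f"nested ATC prefixes in class map: {a!r}, {b!r}")
    return entries


def classify_atc(
    atc_code: str, class_map: Sequence[tuple[str, DrugClass]] | None = None
) -> DrugClass | None:
    """Map an ATC code to its drug class by longest matching prefix.

    Returns ``None`` when no prefix of the map matches (the drug is not an
    antihypertensive of interest).
    """
    if not atc_code:
        raise InputError("atc_code must be non-empty")
    best: DrugClass | None = None
    best_len = -1
    for prefix, cls in _validated_map(class_map):
        if atc_code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = cls, len(prefix)
    return best


def classify_atc_series(
    atc: pd.Series, class_map: Sequence[tuple[str, DrugClass]] | None = None
) -> pd.Series:
    """Vectorised `classify_atc` over a string Series; unmapped codes -> NA."""
    entries = sorted(_validated_map(class_map), key=lambda e: len(e[0]), reverse=True)
    out = pd.Series(pd.NA, index=atc.index, dtype="object")
    for prefix, cls in entries:
        mask = out.isna() & atc.str.startswith(prefix)
        out[mask] = cls
    return out


def prescription_duration_days(units_dispensed: float, daily_number: float) -> int:
    """Days of supply: units / daily number, rounded half-up, minimum 1."""
    if units_dispensed <= 0 or daily_number <= 0:
        raise InputError("units_dispensed and daily_number must be positive")
    return max(1, int(np.floor(units_dispensed / daily_number + 0.5)))


def prescription_end(
    dispense_date: _dt.date, units_dispensed: float, daily_number: float
) -> _dt.date:
    """Theoretical end date of a prescription: the first uncovered day.

    The supply duration is ``units_dispensed / daily_number`` rounded half-up
    to whole days (minimum one day), so a 90-tablet, once-daily prescription
    dispensed on 2000-01-01 covers through 2000-03-30 and ends 2000-03-31.
    """
    return dispense_date + _dt.timedelta(
        days=prescription_duration_days(units_dispensed, daily_number)
    )


# ---------------------------------------------------------------------------
# integer-day helpers (performance: cohort-scale work runs on int64 days)

_EPOCH = _dt.date(1970, 1, 1).toordinal()


def _to_days(s: pd.Series) -> np.ndarray:
    return s.to_numpy(dtype="datetime64[D]").astype(np.int64)


def _day_to_date(day: int) -> _dt.date:
    return _dt.date.fromordinal(int(day) + _EPOCH)


def _date_to_day(d: _dt.date) -> int:
    return d.toordinal() - _EPOCH


def _prepare(dispensings: pd.DataFrame, class_map) -> pd.DataFrame:
    """Annotate a dispensing frame with drug class, day numbers and end days."""
    df = dispensings.copy()
    if (df["units_dispensed"] <= 0).any() or (df["daily_number"] <= 0).any():
        raise InputError("units_dispensed and daily_number must be positive")
    df["drug_class"] = classify_atc_series(df["atc_code"].astype(str), class_map)
    df["_day"] = _to_days(pd.to_datetime(df["dispense_date"]))
    dur = np.maximum(
        1,
        np.floor(
            df["units_dispensed"].to_numpy(float) / df["daily_number"].to_numpy(float)
            + 0.5
        ).astype(np.int64),
    )
    df["_end"] = df["_day"] + dur
    return df


def _followup_index(follow_up: pd.DataFrame) -> pd.DataFrame:
    fu = follow_up.copy()
    fu["_entry"] = _to_days(pd.to_datetime(fu["entry_date"]))
    fu["_exit"] = _to_days(pd.to_datetime(fu["exit_date"]))
    if (fu["_entry"] >= fu["_exit"]).any():
        bad = fu.loc[fu["_entry"] >= fu["_exit"], "patient_id"].iloc[0]
        raise InputError(f"entry_date >= exit_date for patient {bad!r}")
    dup = fu["patient_id"].duplicated()
    if dup.any():
        raise DataIntegrityError(
            f"duplicate follow-up record for patient {fu.loc[dup, 'patient_id'].iloc[0]!r}"
        )
    return fu.set_index("patient_id")


def identify_starters(
    dispensings: pd.DataFrame,
    follow_up: pd.DataFrame,
    study_start: _dt.date = DEFAULT_STUDY_START,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    class_map: Sequence[tuple[str, DrugClass]] | None = None,
) -> set[str]:
    """Identify new users: first-ever ACEI dispensing on/after ``study_start``,
    at least ``lookback_days`` of observed history before it, and no ACEI
    dispensing within that lookback.

    Raises :class:`DataIntegrityError` for dispensings whose patient has no
    follow-up record.
    """
    df = _prepare(dispensings, class_map)
    fu = _followup_index(follow_up)
    missing = set(df["patient_id"]) - set(fu.index)
    if missing:
        raise DataIntegrityError(
            f"dispensings for patients with no follow-up record: {sorted(missing)[:5]}"
        )
    acei = df[df["drug_class"] == DrugClass.ACEI]
    if acei.empty:
        return set()
    # `first` is the first-ever ACEI dispensing in the data, so "no ACEI in
    # the lookback" is implied by first >= study_start together with the
    # history requirement; any earlier ACEI would itself be the minimum.
    first = acei.groupby("patient_id")["_day"].min()
    entry = fu["_entry"].reindex(first.index)
    start_day = _date_to_day(study_start)
    ok = (first >= start_day) & (entry <= first - lookback_days)
    return set(first.index[ok])


def _chain_episode(
    starts: np.ndarray, ends: np.ndarray, gap_days: int
) -> tuple[int, int, int]:
    """Chain sorted ACEI prescriptions; return (start, episode_end, n)."""
    ep_end = int(ends[0])
    n = 1
    for s, e in zip(starts[1:], ends[1:]):
        if s <= ep_end + gap_days:
            ep_end = max(ep_end, int(e))
            n += 1
        else:
            break
    return int(starts[0]), ep_end, n


def build_treatment_episode(
    acei_dispensings: Iterable[DispensingRecord] | pd.DataFrame,
    gap_days: int = 90,
    exit_date: _dt.date | None = None,
) -> TreatmentEpisode:
    """Build the first ACEI treatment episode from sorted ACEI dispensings.

    Each subsequent prescription is chained while its dispense date falls
    within ``gap_days`` of the running episode end; the episode end is the
    running maximum of the chained theoretical end dates.  ``duration_days``
    is measured to ``min(episode_end, exit_date)`` when an exit date is given.
    """
    if isinstance(acei_dispensings, pd.DataFrame):
        df = acei_dispensings
        if df.empty:
            raise InputError("cannot build an episode from zero dispensings")
        recs = [
            DispensingRecord(
                str(r.patient_id),
                str(r.atc_code),
                pd.Timestamp(r.dispense_date).date(),
                float(r.units_dispensed),
                float(r.daily_number),
            )
            for r in df.itertuples()
        ]
    else:
        recs = list(acei_dispensings)
    if not recs:
        raise InputError("cannot build an episode from zero dispensings")
    recs.sort(key=lambda r: r.dispense_date)
    starts = np.array([_date_to_day(r.dispense_date) for r in recs], dtype=np.int64)
    ends = np.array(
        [
            _date_to_day(prescription_end(r.dispense_date, r.units_dispensed, r.daily_number))
            for r in recs
        ],
        dtype=np.int64,
    )
    s, e, n = _chain_episode(starts, ends, gap_days)
    end_day = e if exit_date is None else min(e, _date_to_day(exit_date))
    return TreatmentEpisode(
        patient_id=recs[0].patient_id,
        start_date=_day_to_date(s),
        episode_end=_day_to_date(e),
        n_prescriptions=n,
        duration_days=max(0, end_day - s),
    )


def _classify_days(
    acei_starts: np.ndarray,
    acei_ends: np.ndarray,
    other_days: np.ndarray,
    other_is_arb: np.ndarray,
    other_is_alt: np.ndarray,
    exit_day: int,
    exit_reason: ExitReason,
    gap_days: int,
    switch_window_days: int,
) -> tuple[PatternCategory, int | None, int, int, int]:
    """Core classification on integer days.

    Returns (category, index_day or None, duration_days, ep_start, ep_end).
    """
    start, ep_end, _n = _chain_episode(acei_starts, acei_ends, gap_days)
    duration = max(0, min(ep_end, exit_day) - start)
    if exit_day <= ep_end + gap_days:
        return _EXIT_TO_CATEGORY[exit_reason], None, duration, start, ep_end
    index = ep_end
    hi = min(index + switch_window_days, exit_day)
    in_win = (other_days > index) & (other_days <= hi)
    if bool(np.any(in_win & other_is_arb)):
        cat = PatternCategory.SWITCH_ARB
    elif bool(np.any(in_win & other_is_alt)):
        cat = PatternCategory.SWITCH_OTHER
    else:
        cat = PatternCategory.STOP
    return cat, index, duration, start, ep_end


def classify_pattern(
    patient_id: str,
    dispensings: pd.DataFrame,
    follow_up: FollowUpRecord,
    class_map: Sequence[tuple[str, DrugClass]] | None = None,
    gap_days: int = 90,
    switch_window_days: int | None = None,
) -> PatternResult:
    """Classify one patient's prescription pattern.

    ``dispensings`` holds the patient's full dispensing history (all drug
    classes).  ``switch_window_days`` defaults to ``gap_days``.
    """
    if switch_window_days is None:
        switch_window_days = gap_days
    df = _prepare(dispensings[dispensings["patient_id"] == patient_id], class_map)
    acei = df[df["drug_class"] == DrugClass.ACEI].sort_values("_day")
    if acei.empty:
        raise InputError(f"patient {patient_id!r} has no ACEI dispensings")
    other = df[df["drug_class"] != DrugClass.ACEI]
    is_arb = (other["drug_class"] == DrugClass.ARB).to_numpy()
    is_alt = other["drug_class"].isin(NON_ARB_ALTERNATIVES).to_numpy()
    cat, index, dur, ep_start, ep_end = _classify_days(
        acei["_day"].to_numpy(),
        acei["_end"].to_numpy(),
        other["_day"].to_numpy(),
        is_arb,
        is_alt,
        _date_to_day(follow_up.exit_date),
        follow_up.exit_reason,
        gap_days,
        switch_window_days,
    )
    return PatternResult(
        patient_id=patient_id,
        category=cat,
        index_date=None if index is None else _day_to_date(index),
        acei_duration_days=dur,
        gap_days=gap_days,
        episode_start=_day_to_date(ep_start),
        episode_end=_day_to_date(ep_end),
    )


def classify_cohort(
    dispensings: pd.DataFrame,
    follow_up: pd.DataFrame,
    gap_days: int = 90,
    switch_window_days: int | None = None,
    study_start: _dt.date = DEFAULT_STUDY_START,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    class_map: Sequence[tuple[str, DrugClass]] | None = None,
    starters: set[str] | None = None,
) -> pd.DataFrame:
    """Classify every new user in the cohort at one gap setting.

    Returns a frame with one row per starter: ``patient_id, category,
    index_date, acei_duration_days, gap_days, episode_start, episode_end``.
    Pass a precomputed ``starters`` set to skip the inclusion scan (used when
    classifying the same cohort at several gap settings).
    """
    if switch_window_days is None:
        switch_window_days = gap_days
    if starters is None:
        starters = identify_starters(
            dispensings, follow_up, study_start, lookback_days, class_map
        )
    fu = _followup_index(follow_up)
    if not starters:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "category",
                "index_date",
                "acei_duration_days",
                "gap_days",
                "episode_start",
                "episode_end",
            ]
        )
    df = _prepare(dispensings[dispensings["patient_id"].isin(starters)], class_map)
    df = df.sort_values(["patient_id", "_day"], kind="stable")
    is_acei = (df["drug_class"] == DrugClass.ACEI).to_numpy()
    is_arb = (df["drug_class"] == DrugClass.ARB).to_numpy()
    is_alt = df["drug_class"].isin(NON_ARB_ALTERNATIVES).to_numpy()
    days = df["_day"].to_numpy()
    ends = df["_end"].to_numpy()
    pids = df["patient_id"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, pids[1:] != pids[:-1], True])
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        pid = pids[lo]
        sel = slice(lo, hi)
        a = is_acei[sel]
        exit_day = int(fu.loc[pid, "_exit"])
        reason = ExitReason(fu.loc[pid, "exit_reason"])
        cat, index, dur, ep_start, ep_end = _classify_days(
            days[sel][a],
            ends[sel][a],
            days[sel][~a],
            is_arb[sel][~a],
            is_alt[sel][~a],
            exit_day,
            reason,
            gap_days,
            switch_window_days,
        )
        rows.append(
            (
                pid,
                cat,
                None if index is None else _day_to_date(index),
                dur,
                gap_days,
                _day_to_date(ep_start),
                _day_to_date(ep_end),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "category",
            "index_date",
            "acei_duration_days",
            "gap_days",
            "episode_start",
            "episode_end",
        ],
    )


def reclassification_delta(
    dispensings: pd.DataFrame,
    follow_up: pd.DataFrame,
    gap_a: int,
    gap_b: int,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Compare pattern categories at two gap settings (``gap_a < gap_b``).

    Returns ``(per_patient, transitions, n_to_continuation)`` where
    ``per_patient`` has columns ``patient_id, category_a, category_b``,
    ``transitions`` is the category_a x category_b cross-tabulation and
    ``n_to_continuation`` counts patients moving from a test-positive
    category at ``gap_a`` to a continuation category at ``gap_b``.
    """
    if gap_a > gap_b:
        raise InputError(f"gap_a must be <= gap_b, got {gap_a}, {gap_b}")
    starters = identify_starters(
        dispensings,
        follow_up,
        kwargs.get("study_start", DEFAULT_STUDY_START),
        kwargs.get("lookback_days", DEFAULT_LOOKBACK_DAYS),
        kwargs.get("class_map"),
    )
    common = dict(kwargs)
    common["starters"] = starters
    a = classify_cohort(dispensings, follow_up, gap_days=gap_a, **common)
    b = classify_cohort(dispensings, follow_up, gap_days=gap_b, **common)
    merged = a[["patient_id", "category"]].merge(
        b[["patient_id", "category"]], on="patient_id", suffixes=("_a", "_b")
    )
    cat_a = merged["category_a"].map(lambda c: c.value)
    cat_b = merged["category_b"].map(lambda c: c.value)
    transitions = pd.crosstab(cat_a, cat_b, dropna=False)
    movers = merged[
        merged["category_a"].map(lambda c: c.is_test_positive)
        & merged["category_b"].map(lambda c: c.is_continuation)
    ]
    per_patient = merged.rename(columns={"category_a": "category_a", "category_b": "category_b"})
    return per_patient, transitions, len(movers)
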