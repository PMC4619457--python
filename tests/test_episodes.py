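"""Episode construction and prescription-pattern classification."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from adrproxy.episodes import (
    DEFAULT_CLASS_MAP,
    DispensingRecord,
    DrugClass,
    ExitReason,
    FollowUpRecord,
    PatternCategory,
    build_treatment_episode,
    classify_atc,
    classify_cohort,
    classify_pattern,
    identify_starters,
    prescription_end,
    reclassification_delta,
)
from adrproxy.errors import DataIntegrityError, InputError

from oracles import BASE, CLASS_TO_ATC, day_scan_classify, random_patient

D = dt.date


def disp_frame(rows):
    """rows: (pid, atc, date, units, daily)"""
    return pd.DataFrame(
        rows, columns=["patient_id", "atc_code", "dispense_date", "units_dispensed", "daily_number"]
    )


def fu_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "entry_date", "exit_date", "exit_reason"])


# ---------------------------------------------------------------------------
# ATC classification


@pytest.mark.parametrize(
    "code,expected",
    [
        ("C09AA05", DrugClass.ACEI),
        ("C09BA02", DrugClass.ACEI),
        ("C09CA01", DrugClass.ARB),
        ("C09DA01", DrugClass.ARB),
        ("C07AB02", DrugClass.BETA_BLOCKER),
        ("C08CA01", DrugClass.CCB),
        ("C03AA03", DrugClass.DIURETIC),
        ("C02AC01", DrugClass.OTHER_ANTIHYPERTENSIVE),
        ("C10AA01", None),  # statin
        ("N02BE01", None),
    ],
)
def test_classify_atc_default_map(code, expected):
    assert classify_atc(code) == expected


def test_classify_atc_longest_prefix_and_errors():
    with pytest.raises(InputError):
        classify_atc("")
    # nested prefixes are rejected
    with pytest.raises(InputError):
        classify_atc("C09AA05", [("C09", DrugClass.ACEI), ("C09A", DrugClass.ARB)])
    custom = [("C09A", DrugClass.ACEI), ("C09C", DrugClass.ARB)]
    assert classify_atc("C09AA05", custom) is DrugClass.ACEI
    assert classify_atc("C07AB02", custom) is None


# ---------------------------------------------------------------------------
# theoretical end dates


@pytest.mark.parametrize(
    "date,units,daily,expected",
    [
        (D(2000, 1, 1), 90, 1.0, D(2000, 3, 31)),
        (D(2000, 1, 1), 30, 2.0, D(2000, 1, 16)),
        (D(2000, 1, 1), 1, 1.0, D(2000, 1, 2)),
        (D(2000, 1, 1), 45, 2.0, D(2000, 1, 24)),  # 22.5 rounds half-up to 23
        (D(2000, 1, 1), 1, 4.0, D(2000, 1, 2)),  # minimum one day of coverage
    ],
)
def test_prescription_end(date, units, daily, expected):
    assert prescription_end(date, units, daily) == expected


def test_prescription_end_rejects_nonpositive():
    with pytest.raises(InputError):
        prescription_end(D(2000, 1, 1), 0, 1.0)
    with pytest.raises(InputError):
        prescription_end(D(2000, 1, 1), 30, -1.0)


# ---------------------------------------------------------------------------
# new-user identification


def test_identify_starters_inclusion_rules():
    disp = disp_frame(
        [
            ("A", "C09AA05", D(2000, 3, 1), 30, 1.0),  # clean starter
            ("B", "C09AA05", D(1999, 12, 1), 30, 1.0),  # prior ACEI use
            ("B", "C09AA05", D(2000, 2, 1), 30, 1.0),
            ("C", "C09AA05", D(2000, 3, 1), 30, 1.0),  # only 46 days of history
        ]
    )
    fu = fu_frame(
        [
            ("A", D(1991, 1, 1), D(2011, 1, 1), "END_OF_STUDY"),
            ("B", D(1991, 1, 1), D(2011, 1, 1), "END_OF_STUDY"),
            ("C", D(2000, 1, 15), D(2011, 1, 1), "END_OF_STUDY"),
        ]
    )
    assert identify_starters(disp, fu) == {"A"}


def test_identify_starters_requires_followup():
    disp = disp_frame([("X", "C09AA05", D(2000, 3, 1), 30, 1.0)])
    with pytest.raises(DataIntegrityError):
        identify_starters(disp, fu_frame([]))


# ---------------------------------------------------------------------------
# episode chaining


def ep_record(pid, date, units, daily=1.0):
    return DispensingRecord(pid, "C09AA05", date, units, daily)


def test_episode_chains_within_gap():
    # ends 2001-01-01; renewal 2001-03-15 is 73 days later -> chained
    recs = [ep_record("p", D(2000, 10, 3), 90), ep_record("p", D(2001, 3, 15), 90)]
    ep = build_treatment_episode(recs, gap_days=90)
    assert ep.episode_end == D(2001, 6, 13)
    assert ep.n_prescriptions == 2


def test_episode_closes_at_unchained_renewal():
    # ends 2001-01-01; next dispense 2001-05-01 is 120 days later -> closed
    recs = [ep_record("p", D(2000, 10, 3), 90), ep_record("p", D(2001, 5, 1), 90)]
    ep = build_treatment_episode(recs, gap_days=90)
    assert ep.episode_end == D(2001, 1, 1)
    assert ep.n_prescriptions == 1


def test_episode_single_prescription_and_stockpiling():
    ep = build_treatment_episode([ep_record("p", D(2000, 1, 1), 30)], gap_days=90)
    assert ep.episode_end == D(2000, 1, 31)
    assert ep.duration_days == 30
    # overlapping refill: episode end is the running maximum, not end-to-end
    recs = [
        ep_record("p", D(2000, 1, 1), 90),
        ep_record("p", D(2000, 1, 15), 30),
    ]
    ep = build_treatment_episode(recs, gap_days=90)
    assert ep.episode_end == D(2000, 3, 31)


def test_episode_empty_input():
    with pytest.raises(InputError):
        build_treatment_episode([], gap_days=90)


# ---------------------------------------------------------------------------
# pattern classification


def _classify(disp_rows, fu_row, gap=90, window=None):
    return classify_pattern(
        fu_row[0], disp_frame(disp_rows), FollowUpRecord(*fu_row), gap_days=gap,
        switch_window_days=window,
    )


def test_switch_to_arb():
    rows = [
        ("p", "C09AA05", D(2005, 3, 3), 90, 1.0),  # ends 2005-06-01
        ("p", "C09CA01", D(2005, 7, 15), 90, 1.0),
    ]
    res = _classify(rows, ("p", D(1995, 1, 1), D(2011, 1, 1), ExitReason.END_OF_STUDY))
    assert res.category is PatternCategory.SWITCH_ARB
    assert res.index_date == D(2005, 6, 1)


def test_switch_to_other_and_arb_precedence():
    rows = [
        ("p", "C09AA05", D(2005, 3, 3), 90, 1.0),
        ("p", "C07AB02", D(2005, 6, 20), 30, 1.0),
    ]
    res = _classify(rows, ("p", D(1995, 1, 1), D(2011, 1, 1), ExitReason.END_OF_STUDY))
    assert res.category is PatternCategory.SWITCH_OTHER
    # an ARB anywhere in the window outranks the beta blocker
    rows.append(("p", "C09CA01", D(2005, 8, 1), 90, 1.0))
    res = _classify(rows, ("p", D(1995, 1, 1), D(2011, 1, 1), ExitReason.END_OF_STUDY))
    assert res.category is PatternCategory.SWITCH_ARB


def test_continuation_until_study_end():
    rows = [("p", "C09AA05", D(2010, 9, 21), 90, 1.0)]  # covers until 2010-12-20
    res = _classify(rows, ("p", D(1995, 1, 1), D(2011, 1, 1), ExitReason.END_OF_STUDY))
    assert res.category is PatternCategory.CONT_END_OF_STUDY
    assert res.index_date is None


@pytest.mark.parametrize(
    "reason,expected",
    [
        (ExitReason.END_OF_STUDY, PatternCategory.CONT_END_OF_STUDY),
        (ExitReason.MOVED_OUT, PatternCategory.CONT_OUT_OF_STUDY),
        (ExitReason.DEATH, PatternCategory.CONT_DEATH),
    ],
)
def test_continuation_subdivided_by_exit_reason(reason, expected):
    rows = [("p", "C09AA05", D(2005, 1, 1), 90, 1.0)]
    res = _classify(rows, ("p", D(1995, 1, 1), D(2005, 5, 1), reason))
    assert res.category is expected


def test_stop_when_no_dispensing_in_window():
    rows = [("p", "C09AA05", D(2005, 1, 1), 90, 1.0)]
    res = _classify(rows, ("p", D(1995, 1, 1), D(2011, 1, 1), ExitReason.END_OF_STUDY))
    assert res.category is PatternCategory.STOP
    assert res.index_date == D(2005, 4, 1)
    assert res.acei_duration_days == 90


def test_dispensing_after_exit_does_not_count_in_window():
    # with a 180-day window pinned over a 90-day gap, an ARB dispensing
    # inside the window but after the exit date must not count
    rows = [
        ("p", "C09AA05", D(2005, 1, 1), 90, 1.0),  # index 2005-04-01
        ("p", "C09CA01", D(2005, 8, 1), 90, 1.0),  # in window, after exit
    ]
    res = _classify(
        rows, ("p", D(1995, 1, 1), D(2005, 7, 15), ExitReason.DEATH), gap=90, window=180
    )
    assert res.category is PatternCategory.STOP


# ---------------------------------------------------------------------------
# oracle equivalence + invariants


def test_day_scan_oracle_equivalence():
    """Episode chaining must agree with a day-by-day coverage simulation."""
    rng = np.random.default_rng(2024)
    for _ in range(400):
        acei, others, exit_day, reason, gap, window = random_patient(rng)
        expected = day_scan_classify(
            [(d, dur) for d, _, _, dur in acei], others, exit_day, reason, gap, window
        )
        rows = [
            ("p", CLASS_TO_ATC[DrugClass.ACEI], BASE + dt.timedelta(days=d), u, dn)
            for d, u, dn, _ in acei
        ] + [
            ("p", CLASS_TO_ATC[c], BASE + dt.timedelta(days=d), 30, 1.0) for d, c in others
        ]
        res = classify_pattern(
            "p",
            disp_frame(rows),
            FollowUpRecord("p", BASE - dt.timedelta(days=400),
                           BASE + dt.timedelta(days=exit_day), reason),
            gap_days=gap,
            switch_window_days=window,
        )
        cat, index, ep_end = expected
        assert res.category is cat
        assert res.episode_end == BASE + dt.timedelta(days=ep_end)
        if index is None:
            assert res.index_date is None
        else:
            assert res.index_date == BASE + dt.timedelta(days=index)
            # index date is inside follow-up and never before the first dispense
            assert BASE <= res.index_date <= BASE + dt.timedelta(days=exit_day)


def test_categories_exhaustive_and_monotone(classified):
    patterns = classified["patterns"]
    n = len(classified["starters"])
    for gap, df in patterns.items():
        assert len(df) == n, f"categories must partition the cohort at gap {gap}"
    cont90 = {
        r.patient_id for r in patterns[90].itertuples() if r.category.is_continuation
    }
    cont180 = {
        r.patient_id for r in patterns[180].itertuples() if r.category.is_continuation
    }
    assert cont90 <= cont180


def test_reclassification_delta_moves_to_continuation():
    # a 120-day break in refills then resumption: STOP at 90 days, continuer at 180
    rows = [
        ("p", "C09AA05", D(2005, 1, 1), 90, 1.0),  # ends 2005-04-01
        ("p", "C09AA05", D(2005, 7, 30), 90, 1.0),  # 120-day gap, then refills resume
        ("p", "C09AA05", D(2005, 10, 25), 90, 1.0),
    ]
    disp = disp_frame(rows)
    fu = fu_frame([("p", D(1995, 1, 1), D(2006, 2, 1), "END_OF_STUDY")])
    per_patient, transitions, movers = reclassification_delta(disp, fu, 90, 180)
    assert movers == 1
    assert per_patient.loc[0, "category_a"] is PatternCategory.STOP
    assert per_patient.loc[0, "category_b"] is PatternCategory.CONT_END_OF_STUDY
    # identical gaps: nobody moves
    _, _, movers_same = reclassification_delta(disp, fu, 90, 90)
    assert movers_same == 0


def test_classify_cohort_matches_per_patient(classified):
    """The vectorised cohort path agrees with single-patient classification."""
    coh = classified["cohort"]
    fu = coh.follow_up.set_index("patient_id")
    sample = sorted(classified["starters"])[:25]
    df180 = classified["patterns"][180].set_index("patient_id")
    for pid in sample:
        row = fu.loc[pid]
        res = classify_pattern(
            pid,
            coh.dispensing[coh.dispensing["patient_id"] == pid],
            FollowUpRecord(
                pid,
                row["entry_date"].date(),
                row["exit_date"].date(),
                ExitReason(row["exit_reason"]),
            ),
            gap_days=180,
        )
        assert res.category == df180.loc[pid, "category"]
        assert res.acei_duration_days == df180.loc[pid, "acei_duration_days"]
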