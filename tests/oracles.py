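"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's episode-chaining and interval code
paths: the classifier below walks the calendar day by day marking covered
days, and the Wilson oracle solves the score equation by bisection.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
from scipy.stats import norm

from adrproxy.episodes import DrugClass, ExitReason, PatternCategory

BASE = dt.date(2000, 6, 1)

CLASS_TO_ATC = {
    DrugClass.ACEI: "C09AA05",
    DrugClass.ARB: "C09CA01",
    DrugClass.BETA_BLOCKER: "C07AB02",
    DrugClass.CCB: "C08CA01",
    DrugClass.DIURETIC: "C03AA03",
    DrugClass.OTHER_ANTIHYPERTENSIVE: "C02AC01",
    None: "C10AA01",  # statin: must be ignored by the switch scan
}

_ALT = {
    DrugClass.BETA_BLOCKER,
    DrugClass.CCB,
    DrugClass.DIURETIC,
    DrugClass.OTHER_ANTIHYPERTENSIVE,
}

_EXIT_TO_CAT = {
    ExitReason.END_OF_STUDY: PatternCategory.CONT_END_OF_STUDY,
    ExitReason.MOVED_OUT: PatternCategory.CONT_OUT_OF_STUDY,
    ExitReason.DEATH: PatternCategory.CONT_DEATH,
}


def day_scan_classify(acei, others, exit_day, exit_reason, gap_days, window_days):
    """Day-by-day coverage simulation.

    ``acei``: list of (dispense_day, duration_days); ``others``: list of
    (day, DrugClass-or-None).  Marks each covered day of each accepted
    prescription and closes the episode at the first uncovered stretch
    longer than ``gap_days``.  Returns (category, index_day or None,
    episode_end_day).
    """
    acei = sorted(acei)
    pres: dict[int, list[int]] = {}
    for d, dur in acei:
        pres.setdefault(d, []).append(dur)
    first = acei[0][0]
    covered: set[int] = set()
    last_covered = None
    d = first
    while True:
        ep_end = first if last_covered is None else last_covered + 1
        if d in pres and d <= ep_end + gap_days:
            for dur in pres[d]:
                covered.update(range(d, d + dur))
            last_covered = max(covered)
        if last_covered is not None and d > last_covered + 1 + gap_days:
            break
        d += 1
    ep_end = last_covered + 1
    if exit_day <= ep_end + gap_days:
        return _EXIT_TO_CAT[exit_reason], None, ep_end
    index = ep_end
    hi = min(index + window_days, exit_day)
    in_window = [c for day, c in others if index < day <= hi]
    if DrugClass.ARB in in_window:
        cat = PatternCategory.SWITCH_ARB
    elif any(c in _ALT for c in in_window):
        cat = PatternCategory.SWITCH_OTHER
    else:
        cat = PatternCategory.STOP
    return cat, index, ep_end


def random_patient(rng: np.random.Generator):
    """A random small dispensing history with stockpiling, gaps, non-ACEI
    dispensings and a random censoring time; returns everything both the
    oracle and the implementation need."""
    n_acei = int(rng.integers(1, 8))
    acei = []  # (day, units, daily, duration)
    day = 0
    for _ in range(n_acei):
        units = int(rng.integers(1, 140))
        daily = float(rng.choice([0.5, 1.0, 1.5, 2.0, 3.0]))
        dur = max(1, math.floor(units / daily + 0.5))
        acei.append((day, units, daily, dur))
        day = day + dur + int(rng.integers(-(dur // 2), 221))
    exit_day = int(rng.integers(10, 1201))
    acei = [a for a in acei if a[0] <= exit_day] or [acei[0]]
    if acei[0][0] > exit_day:  # keep at least one dispensing in follow-up
        exit_day = acei[0][0] + int(rng.integers(1, 400))
    horizon = max(exit_day, max(a[0] + a[3] for a in acei)) + 400
    others = []
    for _ in range(int(rng.integers(0, 7))):
        cls = [
            DrugClass.ARB,
            DrugClass.BETA_BLOCKER,
            DrugClass.CCB,
            DrugClass.DIURETIC,
            DrugClass.OTHER_ANTIHYPERTENSIVE,
            None,
        ][int(rng.integers(6))]
        d = int(rng.integers(0, horizon))
        if d <= exit_day:
            others.append((d, cls))
    exit_reason = [ExitReason.END_OF_STUDY, ExitReason.MOVED_OUT, ExitReason.DEATH][
        int(rng.integers(3))
    ]
    gap = int(rng.choice([30, 90, 180]))
    window = int(rng.choice([90, gap]))
    return acei, others, exit_day, exit_reason, gap, window


def wilson_bisect(k: int, n: int, conf: float = 0.95, tol: float = 1e-12):
    """Wilson interval by bisection on the score statistic."""
    z = norm.ppf(1 - (1 - conf) / 2)
    phat = k / n

    def stat(p):
        return (phat - p) / math.sqrt(p * (1 - p) / n)

    def solve(lo, hi, target):
        for _ in range(200):
            mid = (lo + hi) / 2
            if stat(mid) > target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(1e-15, phat if phat > 0 else 1e-12, z)
    upper = 1.0 if k == n else solve(phat, 1 - 1e-15, -z)
    return lower, upper
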