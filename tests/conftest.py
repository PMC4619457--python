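from __future__ import annotations

import pytest

from adrproxy.adjudication import adjudicate_cohort
from adrproxy.episodes import classify_cohort, identify_starters
from adrproxy.metrics import tabulate
from adrproxy.simulate import SyntheticCohortParams, generate_cohort, table2_fixture


@pytest.fixture(scope="session")
def table2():
    """The published 6-month validation contingency table."""
    return table2_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter synthetic cohort (n = 1132), fixed seed."""
    return generate_cohort(SyntheticCohortParams(), seed=0)


@pytest.fixture(scope="session")
def classified(default_cohort):
    """Starters + pattern classifications of the default cohort at both gap
    settings, with the 180-day adjudication and counts."""
    coh = default_cohort
    starters = identify_starters(coh.dispensing, coh.follow_up)
    patterns = {
        gap: classify_cohort(coh.dispensing, coh.follow_up, gap_days=gap, starters=starters)
        for gap in (90, 180)
    }
    events = coh.gp_events[coh.gp_events["patient_id"].isin(starters)]
    adjud = adjudicate_cohort(patterns[180], events)
    counts = tabulate(patterns[180], adjud)
    return {
        "cohort": coh,
        "starters": starters,
        "patterns": patterns,
        "events": events,
        "adjud": adjud,
        "counts": counts,
    }
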