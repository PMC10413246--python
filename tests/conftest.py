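from datetime import date

import pandas as pd
import pytest

from dxpath.preprocessing import PersonTimeline

EPOCH = pd.Timestamp("2000-01-01")


def make_timeline(person_id, incidents, is_case=False, index_day=5000):
    """Timeline from (category, day-offset) pairs; days count from 2000-01-01."""
    incs = sorted(
        ((c, EPOCH + pd.Timedelta(days=d)) for c, d in incidents),
        key=lambda cd: (cd[1], cd[0]),
    )
    return PersonTimeline(
        person_id=person_id,
        is_case=is_case,
        index_date=EPOCH + pd.Timedelta(days=index_day),
        incidents=incs,
    )


@pytest.fixture
def toy_cohort_timelines():
    """Six hand-written timelines (3 cases, 3 controls) for recount checks."""
    return [
        make_timeline("c1", [("A", 10), ("B", 50), ("C", 90)], is_case=True),
        make_timeline("c2", [("A", 10), ("B", 50), ("C", 90), ("D", 120)], is_case=True),
        make_timeline("c3", [("B", 5), ("A", 30), ("C", 80)], is_case=True),
        make_timeline("k1", [("A", 10), ("C", 50)], is_case=False),
        make_timeline("k2", [("C", 10), ("B", 40), ("A", 70)], is_case=False),
        make_timeline("k3", [], is_case=False),
    ]


def events_frame(rows):
    """Event table from (person_id, day, code, setting) tuples."""
    df = pd.DataFrame(rows, columns=["person_id", "day", "code", "setting"])
    df["date"] = EPOCH + pd.to_timedelta(df.pop("day"), unit="D")
    return df[["person_id", "date", "code", "setting"]]
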