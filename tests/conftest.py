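"""Shared fixtures: hand-built worked examples and small synthetic cohorts."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from tspsleep import SleepSegment, TypicalSleepPeriod, build_record_set

DAY0 = datetime(2024, 3, 1)


def asleep(person: str, start: datetime, minutes: float, level: str = "asleep",
           **kw) -> SleepSegment:
    return SleepSegment(person, start, int(minutes * 60), level, **kw)


def at(day: int, hour: int, minute: int = 0) -> datetime:
    return DAY0 + timedelta(days=day, hours=hour, minutes=minute)


@pytest.fixture
def four_log_example():
    """Four logs across two days: two daytime sleeps and a fragmented night.

    C: day 0 10:00-12:00, D: day 0 14:00-15:30, B: day 0 22:00-23:30,
    A: day 1 01:30-06:30. The habitual window spans 22:00-06:30.
    """
    segs = [
        asleep("u", at(0, 10), 120),   # C
        asleep("u", at(0, 14), 90),    # D
        asleep("u", at(0, 22), 90),    # B
        asleep("u", at(1, 1, 30), 300),  # A
    ]
    rs = build_record_set("u", segs)
    names = dict(zip(sorted(lg.log_id for lg in rs.logs), "CDBA"))
    tsp = TypicalSleepPeriod("u", msp=2 * 60 + 15, tsp_bt=22 * 60,
                             tsp_wt=6 * 60 + 30, n_support_logs=10)
    return rs, tsp, names


@pytest.fixture
def disrupted_night():
    """Night sleep 22:00-23:30 and 01:30-06:30 with a 2 h wake gap."""
    segs = [asleep("d", at(0, 22), 90), asleep("d", at(1, 1, 30), 300)]
    return build_record_set("d", segs)
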