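"""Per-night and per-day sleep metrics from classified logs.

Conventions (config-overridable where noted):

* TATS (time attempting to sleep) = waketime − bedtime of the primary
  sleep period, imputed wake gaps included.
* TST (total sleep time) = summed minutes of sleep-level segments
  (``asleep`` / ``light`` / ``deep`` / ``rem``) across component logs.
* total wake = TATS − TST (exact, integer-second arithmetic).
* WASO (wake after sleep onset) = within-log wake minutes occurring
  after the first sleep-level segment of the period, plus all imputed
  gap minutes. Pre-onset wake is excluded; ``restless`` counts as wake.
* NWAK = number of within-log wake *episodes* (maximal wake runs) after
  sleep onset, plus the number of imputed gaps.
* sleep efficiency = 100 · TST / TATS, missing when TST = 0.
* stage minutes (light/deep/REM) are summed over staged segments only
  and reported missing when the period has none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

import pandas as pd

from .classify import ClassifiedLog, PrimarySleepPeriod
from .model import STAGED_SLEEP, SleepRecordSet, WAKE_LEVELS

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "tats_min", "tst_min", "waso_min", "nwak", "total_wake_min",
    "sleep_efficiency_pct", "light_min", "deep_min", "rem_min",
]


@dataclass
class NightMetrics:
    """Metric vector for one primary sleep period under one algorithm."""

    person_id: str
    night_date: date
    algorithm: str
    bedtime: object
    waketime: object
    tats_min: float
    tst_min: float
    waso_min: float
    nwak: int
    total_wake_min: float
    sleep_efficiency_pct: Optional[float]
    light_min: Optional[float]
    deep_min: Optional[float]
    rem_min: Optional[float]
    hybrid_stitched: bool
    n_component_logs: int


@dataclass
class DayNonPrimaryMetrics:
    """Nap accounting: nonprimary sleep on one day under one algorithm."""

    person_id: str
    day: date
    algorithm: str
    nonprimary_tst_min: float
    nonprimary_count: int


def compute_night_metrics(period: PrimarySleepPeriod,
                          algorithm: str = "tsp",
                          restless_is_wake: bool = True) -> NightMetrics:
    """Compute the per-night metric vector for one primary sleep period."""
    wake_levels = WAKE_LEVELS if restless_is_wake else WAKE_LEVELS - {"restless"}
    segs = sorted((s for lg in period.component_logs for s in lg.segments),
                  key=lambda s: s.start)
    tats_s = (period.waketime - period.bedtime).total_seconds()
    tst_s = sum(s.duration_s for s in segs if s.is_sleep)

    onset = next((s.start for s in segs if s.is_sleep), None)
    waso_s = 0.0
    nwak = 0
    in_wake_run = False
    for s in segs:
        if onset is not None and s.level in wake_levels and s.start >= onset:
            waso_s += s.duration_s
            if not in_wake_run:
                nwak += 1
            in_wake_run = True
        else:
            in_wake_run = False
    gap_s = sum((b - a).total_seconds() for a, b in period.imputed_gaps)
    waso_s += gap_s
    nwak += len(period.imputed_gaps)

    if tst_s == 0:
        logger.warning("zero-TST primary period %s/%s: efficiency undefined",
                       period.person_id, period.night_date)
        efficiency = None
    else:
        efficiency = 100.0 * tst_s / tats_s

    stage_s = {lvl: 0 for lvl in STAGED_SLEEP}
    has_staged = False
    for s in segs:
        if s.level in STAGED_SLEEP:
            stage_s[s.level] += s.duration_s
            has_staged = True

    return NightMetrics(
        person_id=period.person_id,
        night_date=period.night_date,
        algorithm=algorithm,
        bedtime=period.bedtime,
        waketime=period.waketime,
        tats_min=tats_s / 60.0,
        tst_min=tst_s / 60.0,
        waso_min=waso_s / 60.0,
        nwak=nwak,
        total_wake_min=(tats_s - tst_s) / 60.0,
        sleep_efficiency_pct=efficiency,
        light_min=stage_s["light"] / 60.0 if has_staged else None,
        deep_min=stage_s["deep"] / 60.0 if has_staged else None,
        rem_min=stage_s["rem"] / 60.0 if has_staged else None,
        hybrid_stitched=period.hybrid_stitched,
        n_component_logs=len(period.component_logs),
    )


def compute_nonprimary_metrics(classified_logs: Sequence[ClassifiedLog],
                               day: date,
                               algorithm: str = "tsp") -> DayNonPrimaryMetrics:
    """Sum TST and count of nonprimary logs anchored to ``day``."""
    naps = [cl for cl in classified_logs
            if not cl.is_primary(algorithm) and cl.night_date(algorithm) == day]
    person = classified_logs[0].person_id if classified_logs else ""
    return DayNonPrimaryMetrics(
        person_id=person,
        day=day,
        algorithm=algorithm,
        nonprimary_tst_min=sum(cl.log.tst_minutes for cl in naps),
        nonprimary_count=len(naps),
    )


def nights_frame(metrics: Sequence[NightMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-night-per-algorithm table."""
    rows = [{
        "person_id": m.person_id, "night_date": m.night_date,
        "algorithm": m.algorithm, "bedtime": m.bedtime, "waketime": m.waketime,
        "tats_min": m.tats_min, "tst_min": m.tst_min, "waso_min": m.waso_min,
        "nwak": m.nwak, "total_wake_min": m.total_wake_min,
        "sleep_efficiency_pct": math.nan if m.sleep_efficiency_pct is None else m.sleep_efficiency_pct,
        "light_min": math.nan if m.light_min is None else m.light_min,
        "deep_min": math.nan if m.deep_min is None else m.deep_min,
        "rem_min": math.nan if m.rem_min is None else m.rem_min,
        "hybrid_stitched": m.hybrid_stitched,
        "n_component_logs": m.n_component_logs,
    } for m in metrics]
    cols = ["person_id", "night_date", "algorithm", "bedtime", "waketime",
            *METRIC_COLUMNS, "hybrid_stitched", "n_component_logs"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["person_id", "night_date", "algorithm"]).reset_index(drop=True)


def nonprimary_frame(classified_logs: Sequence[ClassifiedLog],
                     algorithm: str) -> pd.DataFrame:
    """Per-day nonprimary TST and counts for one person under one algorithm.

    Every day with at least one log is reported, with zeros on days
    whose logs are all primary, so per-day means are unbiased.
    """
    days = sorted({cl.night_date(algorithm) for cl in classified_logs})
    rows = [vars(compute_nonprimary_metrics(classified_logs, d, algorithm))
            for d in days]
    return pd.DataFrame(rows, columns=["person_id", "day", "algorithm",
                                       "nonprimary_tst_min", "nonprimary_count"])


def daily_tst_hours(record_set: SleepRecordSet) -> pd.Series:
    """Total recorded sleep (all logs, hours) per calendar day of log end."""
    acc: dict[date, float] = {}
    for lg in record_set.logs:
        d = lg.end.date()
        acc[d] = acc.get(d, 0.0) + lg.tst_minutes / 60.0
    return pd.Series(acc, dtype=float).sort_index()


def sufficiency_filter(record_sets: Sequence[SleepRecordSet],
                       min_hours: float = 4.0,
                       max_bad_fraction: float = 0.30,
                       ) -> tuple[list[SleepRecordSet], pd.DataFrame]:
    """Exclude persons with too little recorded sleep on too many days.

    A person is excluded iff the fraction of their monitored days (days
    with any recorded sleep) on which total recorded sleep is below
    ``min_hours`` strictly exceeds ``max_bad_fraction``; a person at
    exactly the threshold is retained.
    """
    kept: list[SleepRecordSet] = []
    rows = []
    for rs in record_sets:
        tst = daily_tst_hours(rs)
        frac = float((tst < min_hours).mean()) if len(tst) else 1.0
        excluded = frac > max_bad_fraction
        rows.append({"person_id": rs.person_id, "n_days": len(tst),
                     "bad_fraction": frac, "excluded": excluded})
        if not excluded:
            kept.append(rs)
    report = pd.DataFrame(rows, columns=["person_id", "n_days",
                                         "bad_fraction", "excluded"])
    return kept, report
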