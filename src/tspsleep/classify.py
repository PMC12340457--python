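"""Primary-sleep-log classification: calendar-relative and user-centric.

Two algorithms label each reconstructed sleep log as primary or
nonprimary sleep:

* **isMainSleep** (calendar-relative baseline): on each calendar day,
  the longest-duration log *ending* that day is the primary sleep log.
  Simple, but a night interrupted by >= 1 h of wakefulness is split into
  several logs of which only the longest is kept, and naps can displace
  true night sleep.

* **TSP** (user-centric): a per-person *typical sleep period* — the
  habitual window [TSP bedtime, TSP wake time] on the 24 h clock —
  is derived from the person's own history (median bed/wake times of
  daily-longest logs around the median midsleep point). Any log of at
  least 1 h that overlaps a nightly instantiation of this window (or
  ends within 1 h of in-window sleep that night) is primary; all logs of
  one night are then *stitched* into a single primary sleep period,
  and out-of-window logs that isMainSleep had promoted are *cleaned*
  back to nonprimary.

The 2x2 of the two labels gives the reclassification category of each
log: A = primary under both (no change), B = stitched (TSP only),
C = cleaned (isMainSleep only), D = nonprimary under both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

from . import clock
from .model import SleepLog, SleepRecordSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 5
DEFAULT_RELEVANCE_HALFWIDTH_H = 4.0
MIN_PRIMARY_LOG_MIN = 60.0
RESCUE_GAP_MIN = 60.0


class TSPUnavailableError(RuntimeError):
    """Raised when a person's history cannot support a typical sleep period."""


@dataclass(frozen=True)
class TypicalSleepPeriod:
    """Per-person habitual sleep window on the 24 h clock circle."""

    person_id: str
    msp: float            #: median midsleep point, minutes since midnight
    tsp_bt: float         #: typical bedtime (clock minutes)
    tsp_wt: float         #: typical wake time (clock minutes)
    n_support_logs: int

    def __post_init__(self) -> None:
        length = clock.forward_arc(self.tsp_bt, self.tsp_wt)
        if not (0 < length < clock.DAY_MIN):
            raise TSPUnavailableError(
                f"degenerate TSP window for {self.person_id}: bt == wt"
            )
        if clock.forward_arc(self.tsp_bt, self.msp) > length:
            logger.warning("MSP of %s lies outside [TSP BT, TSP WT]", self.person_id)

    @property
    def length_min(self) -> float:
        return clock.forward_arc(self.tsp_bt, self.tsp_wt)


@dataclass
class ClassifiedLog:
    """One sleep log with both algorithms' labels and night anchors."""

    log: SleepLog
    is_main_sleep: bool
    night_date_ismain: date
    tsp_primary: bool
    night_date_tsp: date
    tsp_fallback: bool = False

    @property
    def log_id(self) -> str:
        return self.log.log_id

    @property
    def person_id(self) -> str:
        return self.log.person_id

    @property
    def reclass_category(self) -> str:
        """2x2 cell: A no-change primary, B stitched, C cleaned, D no-change nonprimary."""
        if self.is_main_sleep and self.tsp_primary:
            return "A"
        if not self.is_main_sleep and self.tsp_primary:
            return "B"
        if self.is_main_sleep and not self.tsp_primary:
            return "C"
        return "D"

    def night_date(self, algorithm: str) -> date:
        if algorithm == "ismain":
            return self.night_date_ismain
        if algorithm == "tsp":
            return self.night_date_tsp
        raise ValueError(f"unknown algorithm {algorithm!r}")

    def is_primary(self, algorithm: str) -> bool:
        return self.is_main_sleep if algorithm == "ismain" else self.tsp_primary


@dataclass
class PrimarySleepPeriod:
    """One night's primary sleep: component logs plus imputed wake gaps."""

    person_id: str
    night_date: date
    component_logs: list[SleepLog]
    imputed_gaps: list[tuple[datetime, datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.component_logs = sorted(self.component_logs, key=lambda lg: lg.start)
        self.imputed_gaps = [
            (a.end, b.start)
            for a, b in zip(self.component_logs, self.component_logs[1:])
        ]

    @property
    def bedtime(self) -> datetime:
        return self.component_logs[0].start

    @property
    def waketime(self) -> datetime:
        return max(lg.end for lg in self.component_logs)

    @property
    def hybrid_stitched(self) -> bool:
        families = {lg.family for lg in self.component_logs}
        return "hybrid" in families or families >= {"classic", "staged"}


# ---------------------------------------------------------------------------
# calendar-relative baseline


def daily_longest_logs(record_set: SleepRecordSet) -> dict[date, SleepLog]:
    """Longest-duration log ending on each calendar day (ties: earliest end)."""
    best: dict[date, SleepLog] = {}
    for lg in sorted(record_set.logs, key=lambda lg: lg.end):
        day = lg.end.date()
        if day not in best or lg.duration_minutes > best[day].duration_minutes:
            best[day] = lg
    return best


def classify_is_main_sleep(record_set: SleepRecordSet) -> dict[str, tuple[bool, date]]:
    """Label each log under the calendar-relative rule.

    Returns ``{log_id: (is_main_sleep, night_date)}`` where the night is
    the calendar date on which the log ends.
    """
    primary_ids = {lg.log_id for lg in daily_longest_logs(record_set).values()}
    return {
        lg.log_id: (lg.log_id in primary_ids, lg.end.date())
        for lg in record_set.logs
    }


# ---------------------------------------------------------------------------
# user-centric TSP derivation


def log_midsleep(lg: SleepLog) -> float:
    """Clock time halfway between a log's bedtime and wake time."""
    return clock.wrap(clock.clock_minutes(lg.start) + lg.duration_minutes / 2.0)


def compute_msp(candidate_logs: Sequence[SleepLog],
                min_support: int = DEFAULT_MIN_SUPPORT) -> float:
    """Median midsleep point (circular) of the daily-longest candidate logs."""
    if len(candidate_logs) < min_support:
        raise TSPUnavailableError(
            f"need >= {min_support} candidate logs, got {len(candidate_logs)}"
        )
    return clock.circ_median([log_midsleep(lg) for lg in candidate_logs])


def derive_tsp(record_set: SleepRecordSet,
               relevance_halfwidth_h: float = DEFAULT_RELEVANCE_HALFWIDTH_H,
               min_support: int = DEFAULT_MIN_SUPPORT,
               rolling_window_days: Optional[int] = None) -> TypicalSleepPeriod:
    """Derive a person's typical sleep period from their log history.

    Pipeline: candidates are the daily longest logs; the median midsleep
    point (MSP) is their circular median; *relevant* logs are candidates
    whose midsleep point falls within ``relevance_halfwidth_h`` hours of
    the MSP on the clock circle (this is what excludes naps); TSP bedtime
    and wake time are the circular medians of the relevant logs' start
    and end clock times. Raises :class:`TSPUnavailableError` rather than
    guessing when support is insufficient.

    ``rolling_window_days`` optionally restricts candidates to the
    trailing window before the last recorded day (off by default: one
    static TSP per person).
    """
    candidates = list(daily_longest_logs(record_set).values())
    if rolling_window_days is not None and candidates:
        cutoff = max(lg.end for lg in candidates) - timedelta(days=rolling_window_days)
        candidates = [lg for lg in candidates if lg.end >= cutoff]
    msp = compute_msp(candidates, min_support=min_support)
    halfwidth_min = relevance_halfwidth_h * 60.0
    relevant = [lg for lg in candidates
                if clock.circ_dist(log_midsleep(lg), msp) <= halfwidth_min]
    if not relevant:
        raise TSPUnavailableError("no candidate logs near the median midsleep point")
    tsp_bt = clock.circ_median([clock.clock_minutes(lg.start) for lg in relevant])
    tsp_wt = clock.circ_median([clock.clock_minutes(lg.end) for lg in relevant])
    return TypicalSleepPeriod(record_set.person_id, msp, tsp_bt, tsp_wt, len(relevant))


# ---------------------------------------------------------------------------
# user-centric TSP classification


def _overlap_min(a_start: datetime, a_end: datetime,
                 b_start: datetime, b_end: datetime) -> float:
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return max(0.0, (hi - lo).total_seconds() / 60.0)


def nightly_windows(tsp: TypicalSleepPeriod, first_day: date,
                    last_day: date) -> dict[date, tuple[datetime, datetime]]:
    """Instantiate the TSP window for every night in a date range.

    The instance anchored to night ``d`` ends at ``d`` + TSP wake time
    and starts one window-length earlier (possibly on the previous
    calendar day). ``d`` is therefore the wake date of the night.
    """
    length = timedelta(minutes=tsp.length_min)
    windows: dict[date, tuple[datetime, datetime]] = {}
    day = first_day
    while day <= last_day:
        end = datetime.combine(day, clock.to_time(tsp.tsp_wt))
        windows[day] = (end - length, end)
        day += timedelta(days=1)
    return windows


def classify_tsp(record_set: SleepRecordSet,
                 tsp: TypicalSleepPeriod) -> dict[str, tuple[bool, date]]:
    """Label each log under the user-centric rule.

    A log is primary iff it lasts at least 1 h and either overlaps a
    nightly TSP window (anchored to the window with maximal overlap,
    earlier night on ties) or ends within 1 h of the start of the
    earliest TSP-overlapping log of a night (the rescue clause for
    pre-window dozing). Nonprimary logs keep their end date as the day
    anchor used for nonprimary (nap) accounting.
    """
    if not record_set.logs:
        return {}
    windows = nightly_windows(
        tsp,
        record_set.monitoring_start,
        record_set.monitoring_end + timedelta(days=1),
    )
    labels: dict[str, tuple[bool, date]] = {}
    night_onsets: dict[date, datetime] = {}  # earliest overlapping-primary start
    pending: list[SleepLog] = []

    for lg in record_set.logs:
        best_day: Optional[date] = None
        best_ov = 0.0
        for day, (ws, we) in windows.items():
            ov = _overlap_min(lg.start, lg.end, ws, we)
            if ov > best_ov:
                best_ov, best_day = ov, day
        if lg.duration_minutes >= MIN_PRIMARY_LOG_MIN and best_ov > 0.0:
            labels[lg.log_id] = (True, best_day)
            onset = night_onsets.get(best_day)
            if onset is None or lg.start < onset:
                night_onsets[best_day] = lg.start
        else:
            labels[lg.log_id] = (False, lg.end.date())
            if lg.duration_minutes >= MIN_PRIMARY_LOG_MIN:
                pending.append(lg)

    # rescue clause: a >=1 h log ending within 1 h before the first
    # in-window sleep of a night joins that night's primary period
    for lg in pending:
        for day, onset in night_onsets.items():
            gap_min = (onset - lg.end).total_seconds() / 60.0
            if 0.0 <= gap_min <= RESCUE_GAP_MIN:
                labels[lg.log_id] = (True, day)
                break
    return labels


def classify_record_set(record_set: SleepRecordSet,
                        tsp: Optional[TypicalSleepPeriod] = None,
                        relevance_halfwidth_h: float = DEFAULT_RELEVANCE_HALFWIDTH_H,
                        min_support: int = DEFAULT_MIN_SUPPORT,
                        rolling_window_days: Optional[int] = None) -> list[ClassifiedLog]:
    """Run both algorithms on one person and combine the labels.

    If the TSP cannot be derived (short wear history), TSP labels fall
    back to the calendar-relative ones and every log is flagged
    ``tsp_fallback`` — a participant is never silently dropped.
    """
    ismain = classify_is_main_sleep(record_set)
    fallback = False
    if tsp is None:
        try:
            tsp = derive_tsp(record_set, relevance_halfwidth_h, min_support,
                             rolling_window_days)
        except TSPUnavailableError as exc:
            logger.warning("TSP unavailable for %s (%s); using calendar labels",
                           record_set.person_id, exc)
            fallback = True
    tsp_labels = ismain if fallback else classify_tsp(record_set, tsp)
    out = []
    for lg in record_set.logs:
        im, im_day = ismain[lg.log_id]
        tp, tp_day = tsp_labels[lg.log_id]
        out.append(ClassifiedLog(lg, im, im_day, tp, tp_day, tsp_fallback=fallback))
    return out


def stitch_primary_periods(classified_logs: Sequence[ClassifiedLog],
                           algorithm: str = "tsp") -> list[PrimarySleepPeriod]:
    """Assemble primary sleep periods from labeled logs.

    Under TSP, all primary logs sharing a night become one period with
    the inter-log gaps recorded as imputed wake. Under the calendar
    rule each primary log is its own period (the baseline never
    stitches).
    """
    by_night: dict[tuple[str, date], list[SleepLog]] = {}
    for cl in classified_logs:
        if cl.is_primary(algorithm):
            by_night.setdefault((cl.person_id, cl.night_date(algorithm)), []).append(cl.log)
    return [
        PrimarySleepPeriod(person, night, logs)
        for (person, night), logs in sorted(by_night.items())
    ]
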