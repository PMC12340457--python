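"""Domain types for sequence-level wearable sleep data.

The data hierarchy mirrors how consumer wearables export sleep:

* a **segment** is an atomic interval of a single sleep level
  (start timestamp + duration in seconds);
* a **log** is a maximal run of segments separated by less than one
  hour of unrecorded time — the unit that gets classified as primary
  or nonprimary sleep;
* a **record set** is one person's full monitoring history of logs.

Intervals are half-open ``[start, end)``; durations are kept in integer
seconds internally and reported in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: classic (accelerometry-only) vocabulary
CLASSIC_SLEEP = frozenset({"asleep"})
CLASSIC_WAKE = frozenset({"awake", "restless"})
#: staged (heart-rate assisted) vocabulary
STAGED_SLEEP = frozenset({"light", "deep", "rem"})
STAGED_WAKE = frozenset({"wake"})

CLASSIC_LEVELS = CLASSIC_SLEEP | CLASSIC_WAKE
STAGED_LEVELS = STAGED_SLEEP | STAGED_WAKE
ALL_LEVELS = CLASSIC_LEVELS | STAGED_LEVELS
SLEEP_LEVELS = CLASSIC_SLEEP | STAGED_SLEEP
WAKE_LEVELS = CLASSIC_WAKE | STAGED_WAKE

MAX_SEGMENT_SECONDS = 24 * 3600


class SchemaError(ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(ValueError):
    """One or more rows violate the segment invariants."""


def level_family(level: str) -> str:
    """Return ``"classic"`` or ``"staged"`` for a sleep level."""
    if level in CLASSIC_LEVELS:
        return "classic"
    if level in STAGED_LEVELS:
        return "staged"
    raise ValidationError(f"unknown sleep level {level!r}")


def is_sleep_level(level: str) -> bool:
    return level in SLEEP_LEVELS


@dataclass(frozen=True)
class SleepSegment:
    """Atomic interval of one sleep level.

    Parameters
    ----------
    person_id : str
        Opaque participant identifier.
    start : datetime
        Timezone-naive local clock time at which the segment begins.
    duration_s : int
        Segment length in seconds; ``0 < duration_s <= 86400``.
    level : str
        One of the classic levels (``asleep``/``restless``/``awake``)
        or the staged levels (``light``/``deep``/``rem``/``wake``).
    source_log_id : str, optional
        Log identifier carried over from the source export, if any.
    source_is_main : bool, optional
        The exporter's own main-sleep flag, if present.
    """

    person_id: str
    start: datetime
    duration_s: int
    level: str
    source_log_id: Optional[str] = None
    source_is_main: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0 < self.duration_s <= MAX_SEGMENT_SECONDS):
            raise ValidationError(
                f"segment duration must be in (0, 24 h] seconds, got {self.duration_s}"
            )
        level_family(self.level)  # raises on unknown vocabulary

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=self.duration_s)

    @property
    def family(self) -> str:
        return level_family(self.level)

    @property
    def is_sleep(self) -> bool:
        return self.level in SLEEP_LEVELS


@dataclass
class SleepLog:
    """Maximal run of segments with inter-segment gaps < 1 hour."""

    log_id: str
    person_id: str
    segments: list[SleepSegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("a sleep log needs at least one segment")
        self.segments = sorted(self.segments, key=lambda s: s.start)

    @property
    def start(self) -> datetime:
        return self.segments[0].start

    @property
    def end(self) -> datetime:
        return max(s.end for s in self.segments)

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    @property
    def tst_minutes(self) -> float:
        """Summed minutes of sleep-level segments."""
        return sum(s.duration_s for s in self.segments if s.is_sleep) / 60.0

    @property
    def family(self) -> str:
        """``classic`` / ``staged`` if pure, ``hybrid`` if levels mix families."""
        families = {s.family for s in self.segments}
        if families == {"classic"}:
            return "classic"
        if families == {"staged"}:
            return "staged"
        return "hybrid"

    @property
    def source_is_main(self) -> Optional[bool]:
        flags = {s.source_is_main for s in self.segments if s.source_is_main is not None}
        if len(flags) == 1:
            return flags.pop()
        return None


@dataclass
class SleepRecordSet:
    """One person's reconstructed monitoring history."""

    person_id: str
    logs: list[SleepLog] = field(default_factory=list)

    @property
    def monitoring_start(self) -> date:
        return min(lg.start for lg in self.logs).date()

    @property
    def monitoring_end(self) -> date:
        return max(lg.end for lg in self.logs).date()

    @property
    def n_days(self) -> int:
        """Calendar days on which at least one segment starts or ends."""
        days: set[date] = set()
        for lg in self.logs:
            for seg in lg.segments:
                days.add(seg.start.date())
                days.add(seg.end.date())
        return len(days)


def _covered_seconds(segments: Sequence[SleepSegment]) -> int:
    return sum(s.duration_s for s in segments)


def resolve_overlaps(segments: Sequence[SleepSegment]) -> list[SleepSegment]:
    """Drop duplicates and overlapping segments for one person.

    Exact duplicates are removed first; among partially overlapping
    segments, the non-overlapping subset maximizing total covered time is
    kept (weighted interval scheduling with duration as weight, earliest
    start as deterministic tie-break). Emits a warning with counts when
    anything is dropped.
    """
    uniq: dict[tuple, SleepSegment] = {}
    for s in segments:
        uniq.setdefault((s.start, s.duration_s, s.level), s)
    segs = sorted(uniq.values(), key=lambda s: (s.start, s.end))
    n_dupes = len(segments) - len(segs)

    overlapping = any(segs[i].end > segs[i + 1].start for i in range(len(segs) - 1))
    if not overlapping:
        if n_dupes:
            logger.warning("dropped %d exact duplicate segments", n_dupes)
        return segs

    # weighted interval scheduling: maximize covered seconds
    import bisect

    ends = [s.end for s in segs]
    starts = [s.start for s in segs]
    order = sorted(range(len(segs)), key=lambda i: ends[i])
    sorted_ends = [ends[i] for i in order]
    # best[k] = (covered, chosen) over first k intervals in end order
    best: list[tuple[int, tuple[int, ...]]] = [(0, ())]
    for rank, i in enumerate(order):
        # last interval (in end order) ending <= start of i
        j = bisect.bisect_right(sorted_ends, starts[i])
        take = (best[j][0] + segs[i].duration_s, best[j][1] + (i,))
        skip = best[rank]
        best.append(max(take, skip, key=lambda t: (t[0], tuple(-k for k in t[1]))))
    kept_idx = sorted(best[-1][1])
    kept = [segs[i] for i in kept_idx]
    logger.warning(
        "resolved overlapping segments: kept %d of %d (plus %d exact duplicates dropped)",
        len(kept), len(segs), n_dupes,
    )
    return kept


def reconstruct_logs(
    segments: Iterable[SleepSegment],
    gap_threshold_min: float = 60.0,
    log_id_prefix: str = "L",
) -> list[SleepLog]:
    """Group one person's segments into sleep logs.

    Consecutive segments separated by **less than** ``gap_threshold_min``
    minutes of unrecorded time belong to the same log; a gap of at least
    the threshold starts a new log. Overlapping or duplicated segments
    are resolved first (see :func:`resolve_overlaps`).
    """
    segs = list(segments)
    if not segs:
        return []
    persons = {s.person_id for s in segs}
    if len(persons) != 1:
        raise ValidationError(f"segments span multiple persons: {sorted(persons)}")
    person_id = persons.pop()
    segs = resolve_overlaps(segs)

    logs: list[SleepLog] = []
    run: list[SleepSegment] = [segs[0]]
    for seg in segs[1:]:
        gap_min = (seg.start - run[-1].end).total_seconds() / 60.0
        if gap_min < gap_threshold_min:
            run.append(seg)
        else:
            logs.append(SleepLog(f"{person_id}-{log_id_prefix}{len(logs):04d}", person_id, run))
            run = [seg]
    logs.append(SleepLog(f"{person_id}-{log_id_prefix}{len(logs):04d}", person_id, run))
    return logs


def build_record_set(person_id: str, segments: Iterable[SleepSegment],
                     gap_threshold_min: float = 60.0) -> SleepRecordSet:
    return SleepRecordSet(person_id, reconstruct_logs(segments, gap_threshold_min))
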