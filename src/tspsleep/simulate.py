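"""Seeded simulator of longitudinal segment-level sleep data.

The generator emits the same sequence-level schema the readers consume
(one row per segment, classic or staged vocabulary) together with
ground-truth labels, so every pipeline stage is testable without
access-restricted cohort data. It emulates the structural features the
classifiers care about — nights crossing midnight, nights fragmented by
>= 1 h of wakefulness (which the log-reconstruction rule must split into
separate logs), daytime naps, staged levels only for logs of 3 h or
more, and within-log wake interruptions longer than 3 minutes — without
claiming physiological fidelity of the stage sequences themselves.

Archetypes:

* ``regular`` — one uninterrupted log per night around a 23:00–07:00
  habitual window.
* ``fragmented_insomnia`` — nights split into two logs separated by a
  long (>= 60 min) wake gap.
* ``shift_worker`` — daytime sleep (08:00–13:00) plus an evening nap
  (17:00–19:00 window).
* ``napper`` — regular nights plus frequent early-afternoon naps.
* ``mixed`` — moderate fragmentation and occasional naps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clock
from .model import SleepSegment, ValidationError

EPOCH = date(2024, 1, 1)  # arbitrary simulated calendar origin


@dataclass(frozen=True)
class SleeperProfile:
    """Parameters of one simulated sleeper archetype.

    Clock times are minutes since midnight; durations are minutes.
    """

    archetype: str = "regular"
    habitual_bt: float = 23 * 60.0
    habitual_wt: float = 7 * 60.0
    jitter_sd_min: float = 25.0
    p_fragment: float = 0.0
    gap_lognorm_median_min: float = 90.0   # median total gap; support >= 60 min
    gap_lognorm_sigma: float = 0.4
    p_nap: float = 0.0
    nap_window: tuple[float, float] = (13 * 60.0, 15 * 60.0)
    nap_duration_mean_min: float = 60.0
    nap_duration_sd_min: float = 20.0
    p_staged: float = 0.85
    wake_bouts_per_night: float = 1.2      # Poisson mean of within-log wakes
    wake_bout_min: tuple[float, float] = (4.0, 30.0)
    n_days: int = 60
    p_missing_day: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_fragment", "p_nap", "p_staged", "p_missing_day"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        # a nap window overlapping the habitual sleep window is infeasible:
        # the generator could not label the nap as nonprimary ground truth
        night_len = clock.forward_arc(self.habitual_bt, self.habitual_wt)
        for t in self.nap_window:
            if self.p_nap > 0 and clock.forward_arc(self.habitual_bt, t) < night_len:
                raise ValidationError(
                    "nap window overlaps the habitual sleep window")

    @property
    def night_length_min(self) -> float:
        return clock.forward_arc(self.habitual_bt, self.habitual_wt)


def regular_profile(**kw) -> SleeperProfile:
    return SleeperProfile(archetype="regular", **kw)


def fragmented_insomnia_profile(p_fragment: float = 0.6, **kw) -> SleeperProfile:
    return SleeperProfile(archetype="fragmented_insomnia",
                          habitual_bt=22.5 * 60, habitual_wt=6.5 * 60,
                          p_fragment=p_fragment,
                          wake_bouts_per_night=2.5, **kw)


def shift_worker_profile(**kw) -> SleeperProfile:
    return SleeperProfile(archetype="shift_worker",
                          habitual_bt=8 * 60.0, habitual_wt=13 * 60.0,
                          p_nap=0.5, nap_window=(17 * 60.0, 19 * 60.0),
                          nap_duration_mean_min=90.0, **kw)


def napper_profile(**kw) -> SleeperProfile:
    return SleeperProfile(archetype="napper", p_nap=0.7, **kw)


def mixed_profile(**kw) -> SleeperProfile:
    return SleeperProfile(archetype="mixed", p_fragment=0.3, p_nap=0.3, **kw)


ARCHETYPES = {
    "regular": regular_profile,
    "fragmented_insomnia": fragmented_insomnia_profile,
    "shift_worker": shift_worker_profile,
    "napper": napper_profile,
    "mixed": mixed_profile,
}

STAGE_CYCLE = [("light", 35.0), ("deep", 20.0), ("light", 25.0), ("rem", 15.0)]
MIN_STAGED_LOG_MIN = 180.0


def _emit_segments(person_id: str, start: datetime, sleep_min: float,
                   wake_bouts: list[tuple[float, float]],
                   staged: bool, rng: np.random.Generator) -> list[SleepSegment]:
    """Materialize one log: a sleep span with embedded wake bouts.

    ``wake_bouts`` are (offset-from-start, duration) pairs inside the
    span; they replace sleep, so the log's span stays ``sleep_min``.
    """
    start = start.replace(microsecond=0)  # schema is second-precision
    sleep_level_runs: list[tuple[str, float]] = []
    if staged:
        remaining = sleep_min
        i = 0
        while remaining > 0:
            lvl, mean = STAGE_CYCLE[i % len(STAGE_CYCLE)]
            run = float(np.clip(rng.normal(mean, mean / 4), 5.0, remaining))
            sleep_level_runs.append((lvl, run))
            remaining -= run
            i += 1
        wake_level = "wake"
    else:
        sleep_level_runs = [("asleep", sleep_min)]
        wake_level = "restless" if rng.random() < 0.5 else "awake"

    # cut points: wake bout boundaries overlay the sleep-run timeline
    events = sorted(wake_bouts)
    segments: list[SleepSegment] = []
    cursor = 0.0  # offset into the log span

    def add(level: str, dur: float) -> None:
        nonlocal cursor
        dur_s = int(round(dur * 60))
        if dur_s <= 0:
            return
        segments.append(SleepSegment(person_id, start + timedelta(minutes=cursor),
                                     dur_s, level))
        cursor += dur_s / 60.0

    run_iter = iter(sleep_level_runs)
    cur_lvl, cur_left = next(run_iter)
    pos = 0.0
    for off, wdur in events:
        # sleep up to the bout
        need = off - pos
        while need > 1e-9:
            take = min(need, cur_left)
            add(cur_lvl, take)
            cur_left -= take
            need -= take
            if cur_left <= 1e-9:
                try:
                    cur_lvl, cur_left = next(run_iter)
                except StopIteration:
                    cur_left = float("inf")  # pad with last level
            pos = off - need
        add(wake_level, wdur)
        pos = off + wdur
    # trailing sleep
    tail = sleep_min + sum(w for _, w in events) - pos
    while tail > 1e-9 and cur_left > 0:
        take = min(tail, cur_left)
        add(cur_lvl, take)
        cur_left -= take
        tail -= take
        if cur_left <= 1e-9:
            try:
                cur_lvl, cur_left = next(run_iter)
            except StopIteration:
                break
    if tail > 1e-9:
        add(sleep_level_runs[-1][0], tail)
    return segments


def _log_plan(rng: np.random.Generator, profile: SleeperProfile,
              span_min: float) -> list[tuple[float, float]]:
    """Within-log wake bouts > 3 min as (offset, duration) pairs."""
    n = int(rng.poisson(profile.wake_bouts_per_night * span_min
                        / max(profile.night_length_min, 1.0)))
    bouts = []
    lo, hi = profile.wake_bout_min
    for _ in range(n):
        dur = float(rng.uniform(lo, hi))
        off = float(rng.uniform(30.0, max(span_min - dur - 30.0, 31.0)))
        bouts.append((off, dur))
    # drop overlapping bouts (keep earliest)
    bouts.sort()
    kept: list[tuple[float, float]] = []
    for off, dur in bouts:
        if not kept or off >= kept[-1][0] + kept[-1][1] + 5.0:
            if off + dur < span_min - 15.0:
                kept.append((off, dur))
    return kept


def simulate_person(profile: SleeperProfile, seed: int | np.random.Generator,
                    person_id: str = "p0",
                    ) -> tuple[list[SleepSegment], pd.DataFrame]:
    """Simulate one person's monitoring history.

    Returns the flat segment list (schema-valid, reproducible under the
    seed) and a ground-truth table with one row per emitted log:
    ``person_id, night_index, night_date, start, end, true_primary,
    is_nap, staged``. ``night_date`` is the wake date of the night the
    log belongs to (naps carry their own day).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    segments: list[SleepSegment] = []
    truth_rows: list[dict] = []

    def emit_log(start: datetime, sleep_min: float, night_index: int,
                 true_primary: bool, is_nap: bool) -> datetime:
        bouts = [] if is_nap else _log_plan(rng, profile, sleep_min)
        span = sleep_min + sum(d for _, d in bouts)
        staged = span >= MIN_STAGED_LOG_MIN and rng.random() < profile.p_staged
        segs = _emit_segments(person_id, start, sleep_min, bouts, staged, rng)
        end = max(s.end for s in segs)
        segments.extend(segs)
        truth_rows.append({
            "person_id": person_id, "night_index": night_index,
            "night_date": end.date() if true_primary else start.date(),
            "start": start, "end": end,
            "true_primary": true_primary, "is_nap": is_nap, "staged": staged,
        })
        return end

    for day in range(profile.n_days):
        if rng.random() < profile.p_missing_day:
            continue
        bt = profile.habitual_bt + rng.normal(0.0, profile.jitter_sd_min)
        dur = max(profile.night_length_min + rng.normal(0.0, profile.jitter_sd_min),
                  150.0)
        start = datetime.combine(EPOCH + timedelta(days=day), datetime.min.time()) \
            + timedelta(minutes=bt)

        gap = 60.0 + float(rng.lognormal(
            np.log(profile.gap_lognorm_median_min - 60.0), profile.gap_lognorm_sigma))
        # the wake gap is carved out of the in-bed span: a disrupted night
        # still starts near habitual bedtime and ends near habitual wake
        # time, with less sleep in between
        gap = min(gap, dur - 130.0)
        if rng.random() < profile.p_fragment and gap >= 60.0:
            # the awakening falls anywhere in the night (both fragments stay
            # >= 60 min so each remains a classifiable log)
            first = float(rng.uniform(60.0, max(dur - gap - 60.0, 61.0)))
            second = max(dur - first - gap, 60.0)
            first_end = emit_log(start, first, day, True, False)
            emit_log(first_end + timedelta(minutes=gap), second, day, True, False)
        else:
            emit_log(start, dur, day, True, False)

        if rng.random() < profile.p_nap:
            w0, w1 = profile.nap_window
            nap_len = float(np.clip(
                rng.normal(profile.nap_duration_mean_min, profile.nap_duration_sd_min),
                20.0, 150.0))
            latest = clock.forward_arc(w0, w1)
            nap_off = float(rng.uniform(0.0, max(latest - nap_len, 1.0)))
            nap_start = datetime.combine(EPOCH + timedelta(days=day),
                                         datetime.min.time()) \
                + timedelta(minutes=w0 + nap_off)
            emit_log(nap_start, nap_len, day, False, True)

    truth = pd.DataFrame(truth_rows, columns=[
        "person_id", "night_index", "night_date", "start", "end",
        "true_primary", "is_nap", "staged"]).sort_values("start").reset_index(drop=True)
    segments.sort(key=lambda s: s.start)
    return segments, truth


@dataclass
class CohortSpec:
    """Weighted mixture of archetype profiles for a simulated cohort."""

    profiles: Sequence[SleeperProfile]
    weights: Optional[Sequence[float]] = None


def simulate_cohort(spec: CohortSpec | Sequence[SleeperProfile],
                    n_persons: int, seed: int,
                    ) -> tuple[dict[str, list[SleepSegment]], pd.DataFrame]:
    """Simulate a cohort; deterministic under ``seed``.

    Returns ``{person_id: segments}`` plus the concatenated ground-truth
    table (with an ``archetype`` column).
    """
    if n_persons < 1:
        raise ValidationError("n_persons must be >= 1")
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec(list(spec))
    profiles = list(spec.profiles)
    weights = np.asarray(spec.weights if spec.weights is not None
                         else np.ones(len(profiles)), dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[SleepSegment]] = {}
    truths = []
    for i in range(n_persons):
        pid = f"p{i:04d}"
        profile = profiles[int(rng.choice(len(profiles), p=weights))]
        segs, truth = simulate_person(profile, rng, person_id=pid)
        truth["archetype"] = profile.archetype
        cohort[pid] = segs
        truths.append(truth)
    return cohort, pd.concat(truths, ignore_index=True)


def shift_clock(segments: Sequence[SleepSegment],
                hours: float) -> list[SleepSegment]:
    """Rotate every timestamp by a constant offset (for invariance checks)."""
    delta = timedelta(hours=hours)
    return [replace(s, start=s.start + delta) for s in segments]
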