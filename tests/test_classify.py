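"""Both classifiers, TSP derivation, and stitching on worked examples and oracles."""

from datetime import date, datetime, timedelta
from itertools import permutations

import numpy as np
import pytest

from tspsleep import (
    SleepLog,
    SleepRecordSet,
    TSPUnavailableError,
    TypicalSleepPeriod,
    build_record_set,
    classify_is_main_sleep,
    classify_record_set,
    classify_tsp,
    compute_msp,
    derive_tsp,
    stitch_primary_periods,
)
from tspsleep.classify import log_midsleep, nightly_windows
from tspsleep.clock import to_time

from conftest import DAY0, asleep, at


def _primary_ids(labels):
    return {lid for lid, (p, _) in labels.items() if p}


class TestIsMainSleep:
    def test_four_log_example_selects_daytime_and_morning_logs(self, four_log_example):
        rs, _, names = four_log_example
        labels = classify_is_main_sleep(rs)
        assert {names[i] for i in _primary_ids(labels)} == {"C", "A"}
        # night anchored to the calendar day the log ends on
        assert all(d == lg.end.date() for lg, (_, d) in
                   zip(rs.logs, labels.values()))

    def test_single_log_per_day_is_primary(self):
        rs = build_record_set("p", [asleep("p", at(d, 23), 400) for d in range(3)])
        assert _primary_ids(classify_is_main_sleep(rs)) == {lg.log_id for lg in rs.logs}

    def test_equal_duration_tie_goes_to_earlier_ending_log(self):
        # brute force over both presentation orders: the label must not
        # depend on input ordering
        a = asleep("p", at(0, 1), 120)
        b = asleep("p", at(0, 10), 120)
        for order in permutations([a, b]):
            rs = build_record_set("p", list(order))
            winners = [lg for lg in rs.logs
                       if lg.log_id in _primary_ids(classify_is_main_sleep(rs))]
            assert len(winners) == 1 and winners[0].start == a.start

    def test_at_most_one_primary_per_day(self):
        rng = np.random.default_rng(3)
        segs, cursor = [], at(0, 0)
        for _ in range(80):
            cursor += timedelta(minutes=float(rng.uniform(61, 600)))
            segs.append(asleep("p", cursor, float(rng.uniform(30, 400))))
            cursor = segs[-1].end
        rs = build_record_set("p", segs)
        labels = classify_is_main_sleep(rs)
        days = [d for lid, (p, d) in labels.items() if p]
        assert len(days) == len(set(days))


class TestMSPAndTSPDerivation:
    def test_constant_midsleep(self):
        logs = [build_record_set("p", [asleep("p", at(d, 23), 480)]).logs[0]
                for d in range(6)]
        assert compute_msp(logs) == 3 * 60.0  # 23:00 + 4 h

    def test_midsleep_median_across_midnight(self):
        # midsleep points 23:30, 00:30, 01:30 -> 00:30
        starts = [at(0, 19, 30), at(1, 20, 30), at(2, 21, 30)]
        logs = [build_record_set("p", [asleep("p", s, 480)]).logs[0] for s in starts]
        assert compute_msp(logs, min_support=3) == 30.0

    def test_insufficient_support_raises(self):
        logs = [build_record_set("p", [asleep("p", at(0, 23), 480)]).logs[0]]
        with pytest.raises(TSPUnavailableError):
            compute_msp(logs)

    def test_regular_sleeper_recovers_habitual_window(self):
        rs = build_record_set("p", [asleep("p", at(d, 23), 480) for d in range(10)])
        tsp = derive_tsp(rs)
        assert tsp.tsp_bt == 23 * 60 and tsp.tsp_wt == 7 * 60
        assert tsp.n_support_logs == 10

    def test_bedtime_and_waketime_are_circular_medians(self):
        # bedtimes 22:00/23:00/00:00 with 8 h nights -> TSP [23:00, 07:00]
        starts = [at(0, 22), at(1, 23), at(3, 0)]
        rs = build_record_set("p", [asleep("p", s, 480) for s in starts])
        tsp = derive_tsp(rs, min_support=3)
        assert tsp.tsp_bt == 23 * 60 and tsp.tsp_wt == 7 * 60

    def test_naps_excluded_by_relevance_filter(self):
        # adding midday naps must not move the TSP window: their midsleep
        # points are far from the MSP
        nights = [asleep("p", at(d, 23), 480) for d in range(8)]
        naps = [asleep("p", at(d, 13), 50) for d in range(4)]
        with_naps = derive_tsp(build_record_set("p", nights + naps))
        without = derive_tsp(build_record_set("p", nights))
        assert (with_naps.tsp_bt, with_naps.tsp_wt) == (without.tsp_bt, without.tsp_wt)

    def test_shift_worker_msp_in_morning_no_wraparound(self):
        rng = np.random.default_rng(1)
        segs = [asleep("p", at(d, 8) + timedelta(minutes=float(rng.normal(0, 20))), 300)
                for d in range(12)]
        tsp = derive_tsp(build_record_set("p", segs))
        assert 9 * 60 < tsp.msp < 12 * 60  # around 10:30, not near midnight


def brute_force_tsp_labels(rs, tsp):
    """Literal per-(log, night) application of the overlap / rescue rule."""
    length = timedelta(minutes=(tsp.tsp_wt - tsp.tsp_bt) % 1440)
    nights = {}
    day = rs.monitoring_start - timedelta(days=1)
    while day <= rs.monitoring_end + timedelta(days=1):
        end = datetime.combine(day, to_time(tsp.tsp_wt))
        nights[day] = (end - length, end)
        day += timedelta(days=1)

    def overlap(lg, win):
        return max(0.0, (min(lg.end, win[1]) - max(lg.start, win[0])).total_seconds())

    primary = {}
    for lg in rs.logs:
        cands = [(overlap(lg, win), -d.toordinal(), d) for d, win in nights.items()
                 if overlap(lg, win) > 0]
        if lg.duration_minutes >= 60 and cands:
            primary[lg.log_id] = max(cands)[2]
    # rescue: ends within 1 h of the earliest in-window sleep of a night
    onsets = {}
    for lg in rs.logs:
        if lg.log_id in primary:
            d = primary[lg.log_id]
            onsets[d] = min(onsets.get(d, lg.start), lg.start)
    for lg in rs.logs:
        if lg.log_id in primary or lg.duration_minutes < 60:
            continue
        for d, onset in onsets.items():
            if 0 <= (onset - lg.end).total_seconds() <= 3600:
                primary[lg.log_id] = d
                break
    return {lg.log_id: lg.log_id in primary for lg in rs.logs}


class TestClassifyTSP:
    def test_four_log_example_stitches_and_cleans(self, four_log_example):
        rs, tsp, names = four_log_example
        labels = classify_tsp(rs, tsp)
        assert {names[i] for i in _primary_ids(labels)} == {"A", "B"}
        # B is pulled onto the following wake date: both primary logs share a night
        by_name = {names[lid]: v for lid, v in labels.items()}
        assert by_name["B"][1] == by_name["A"][1] == DAY0.date() + timedelta(days=1)

    def test_log_inside_window_is_primary(self):
        rs = build_record_set("p", [asleep("p", at(0, 23, 30), 120)])
        tsp = TypicalSleepPeriod("p", 180.0, 22 * 60, 6 * 60, 5)
        assert _primary_ids(classify_tsp(rs, tsp)) == {rs.logs[0].log_id}

    def test_sub_hour_log_never_primary(self):
        rs = build_record_set("p", [asleep("p", at(0, 23, 30), 45)])
        tsp = TypicalSleepPeriod("p", 180.0, 22 * 60, 6 * 60, 5)
        assert _primary_ids(classify_tsp(rs, tsp)) == set()

    def test_random_logs_match_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        segs, cursor = [], at(0, 0)
        while len(segs) < 500:
            cursor += timedelta(minutes=float(rng.uniform(60, 900)))
            segs.append(asleep("p", cursor, float(rng.uniform(20, 500))))
            cursor = segs[-1].end
        rs = build_record_set("p", segs)
        tsp = TypicalSleepPeriod("p", 150.0, 22.5 * 60, 6.5 * 60, 30)
        got = {lid: p for lid, (p, _) in classify_tsp(rs, tsp).items()}
        assert got == brute_force_tsp_labels(rs, tsp)

    def test_fallback_to_calendar_labels_when_tsp_unavailable(self):
        rs = build_record_set("p", [asleep("p", at(0, 23), 480)])  # 1 night only
        classified = classify_record_set(rs)
        assert all(cl.tsp_fallback for cl in classified)
        assert all(cl.tsp_primary == cl.is_main_sleep for cl in classified)

    def test_time_shift_leaves_tsp_labels_invariant(self):
        rng = np.random.default_rng(5)
        segs = []
        for d in range(12):
            start = at(d, 23) + timedelta(minutes=float(rng.normal(0, 30)))
            segs.append(asleep("p", start, float(rng.uniform(360, 520))))
            if rng.random() < 0.4:
                segs.append(asleep("p", at(d, 14), 45))
        base = {}
        for shift_h in (0, 10):
            shifted = [asleep("p", s.start + timedelta(hours=shift_h),
                              s.duration_s / 60, s.level) for s in segs]
            rs = build_record_set("p", shifted)
            labels = [cl.tsp_primary for cl in
                      sorted(classify_record_set(rs), key=lambda c: c.log.start)]
            base[shift_h] = labels
        assert base[0] == base[10]


class TestStitching:
    def test_disrupted_night_stitches_with_two_hour_gap(self, disrupted_night):
        tsp = TypicalSleepPeriod("d", 135.0, 22 * 60, 6.5 * 60, 8)
        classified = classify_record_set(disrupted_night, tsp=tsp)
        periods = stitch_primary_periods(classified, "tsp")
        assert len(periods) == 1
        p = periods[0]
        assert p.bedtime == at(0, 22) and p.waketime == at(1, 6, 30)
        assert len(p.component_logs) == 2
        (gs, ge), = p.imputed_gaps
        assert (ge - gs).total_seconds() == 120 * 60

    def test_single_log_night_has_no_gaps(self):
        rs = build_record_set("p", [asleep("p", at(d, 23), 480) for d in range(6)])
        classified = classify_record_set(rs)
        for p in stitch_primary_periods(classified, "tsp"):
            assert len(p.component_logs) == 1 and p.imputed_gaps == []

    def test_hybrid_flag_set_when_families_mix(self, disrupted_night):
        segs = [asleep("h", at(0, 22), 90),  # classic short log
                asleep("h", at(1, 1, 30), 300, "light")]  # staged long log
        rs = build_record_set("h", segs)
        tsp = TypicalSleepPeriod("h", 135.0, 22 * 60, 6.5 * 60, 8)
        periods = stitch_primary_periods(classify_record_set(rs, tsp=tsp), "tsp")
        assert len(periods) == 1 and periods[0].hybrid_stitched
        # pure-classic stitching stays unflagged
        pure = stitch_primary_periods(
            classify_record_set(disrupted_night, tsp=tsp), "tsp")
        assert not pure[0].hybrid_stitched


class TestReclassCategories:
    def test_four_log_example_covers_all_cells(self, four_log_example):
        rs, tsp, names = four_log_example
        classified = classify_record_set(rs, tsp=tsp)
        cats = {names[cl.log_id]: cl.reclass_category for cl in classified}
        assert cats == {"A": "A", "B": "B", "C": "C", "D": "D"}

    def test_every_log_in_exactly_one_cell(self):
        rng = np.random.default_rng(9)
        segs, cursor = [], at(0, 0)
        for _ in range(120):
            cursor += timedelta(minutes=float(rng.uniform(61, 700)))
            segs.append(asleep("p", cursor, float(rng.uniform(30, 450))))
            cursor = segs[-1].end
        classified = classify_record_set(build_record_set("p", segs))
        assert all(cl.reclass_category in "ABCD" for cl in classified)
        assert len(classified) == 120

    def test_regular_sleeper_only_no_change_cells(self):
        rs = build_record_set("p", [asleep("p", at(d, 23), 470) for d in range(20)])
        classified = classify_record_set(rs)
        assert {cl.reclass_category for cl in classified} <= {"A", "D"}
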