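"""The four-log worked example: how the two classifiers disagree.

Two calendar days hold four sleep logs: a midday sleep C (10:00-12:00),
an afternoon nap D (14:00-15:30), a pre-midnight log B (22:00-23:30) and
a morning log A (01:30-06:30 the next day). The calendar-relative rule
promotes the longest log ending on each day (C and A); the user-centric
rule, given a habitual window of 22:00-06:30, stitches B with A into one
night and cleans C back to a nap.
"""

from datetime import datetime, timedelta

from tspsleep import (
    SleepSegment,
    TypicalSleepPeriod,
    build_record_set,
    classify_record_set,
    compute_night_metrics,
    stitch_primary_periods,
    variation_score,
)

DAY0 = datetime(2024, 3, 1)


def seg(day, hour, minutes):
    return SleepSegment("u", DAY0 + timedelta(days=day, hours=hour),
                        int(minutes * 60), "asleep")


record_set = build_record_set("u", [
    seg(0, 10.0, 120), seg(0, 14.0, 90), seg(0, 22.0, 90), seg(1, 1.5, 300),
])
names = dict(zip(sorted(lg.log_id for lg in record_set.logs), "CDBA"))
tsp = TypicalSleepPeriod("u", msp=2.25 * 60, tsp_bt=22 * 60,
                         tsp_wt=6.5 * 60, n_support_logs=10)

classified = classify_record_set(record_set, tsp=tsp)
print("log  calendar  user-centric  cell  (A=kept, B=stitched, C=cleaned, D=nap)")
for cl in classified:
    print(f"  {names[cl.log_id]}   {str(cl.is_main_sleep):5}     "
          f"{str(cl.tsp_primary):5}         {cl.reclass_category}")

for period in stitch_primary_periods(classified, "tsp"):
    m = compute_night_metrics(period)
    print(f"\nstitched night {period.night_date}: {period.bedtime:%H:%M} -> "
          f"{period.waketime:%H:%M}")
    print(f"  TATS {m.tats_min:.0f} min, TST {m.tst_min:.0f} min, "
          f"WASO {m.waso_min:.0f} min, NWAK {m.nwak}, "
          f"efficiency {m.sleep_efficiency_pct:.2f}%")

score = variation_score(classified)
print(f"\nvariation score: {score.delta_bar:+.2f} over {score.n_days} days "
      "(stitching on day 1 offsets cleaning on day 0)")
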