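# Methods

## Data model

Sequence-level sleep data arrive as one row per **segment**: a person
identifier, a timezone-naive local start timestamp, a duration in
seconds (0 < d ≤ 24 h), and one sleep level from exactly one vocabulary
family — classic (`asleep`, `restless`, `awake`) or staged (`light`,
`deep`, `rem`, `wake`). Staged levels only occur on sleep periods of
three hours or longer, because staging requires heart-rate data.
Intervals are half-open `[start, end)`; durations are integer seconds
internally and minutes in all reports. Timestamps are taken at face
value as local clock time with no daylight-saving adjustment, because
the source exports carry no zone information.

A **log** is a maximal run of segments whose consecutive gaps are
strictly less than 60 minutes; a gap of 60 minutes or more starts a new
log. Exact duplicate segments are dropped; remaining overlaps (an
artifact of reconstructing logs without a source log identifier) are
resolved by keeping the non-overlapping subset that maximizes total
covered time (weighted interval scheduling), with a logged warning.
This makes reconstruction deterministic: identical input yields
byte-identical serialized output.

## The two classifiers

**Calendar-relative (`isMainSleep`)** — on each calendar day, the
longest-duration log *ending* that day is primary; ties go to the
earlier-ending log for determinism. At most one primary log per
person-day, anchored to the end date.

**User-centric (TSP)** — per person:

1. *Candidates* are the daily longest logs (the same set the calendar
   rule promotes).
2. The **midsleep point** of a log is the clock time at
   bedtime + duration/2, a circular quantity on `[0, 1440)` minutes.
   The person's **MSP** is the circular median of candidate midsleep
   points — the minimizer of summed shortest-arc distances, which is
   always attained at a data point; ties break to the earliest
   minimizer on the clockwise arc from 18:00, a conventional evening
   origin that precedes typical bedtimes. Circularity matters: a linear
   median of midsleep points straddling midnight would land near noon.
3. *Relevant* logs are candidates whose midsleep point lies within
   ±4 h of the MSP on the circle. This is the step that excludes naps.
   The half-width is a parameter (`relevance_halfwidth_h`, default 4):
   half of an 8 h night, wide enough to keep jittered nights, narrow
   enough that a midday nap of a night sleeper is ~10 h away.
4. **TSP bedtime / wake time** are the circular medians of the relevant
   logs' start and end clock times. At least `min_support` (default 5)
   candidate logs are required; otherwise the person gets an explicit
   "TSP unavailable" signal and falls back to calendar labels with a
   `tsp_fallback` flag — nobody is silently dropped. The TSP is static
   over the whole monitoring window by default; an optional
   `rolling_window_days` restricts candidates to a trailing window for
   long histories where the habitual schedule may drift.

Classification instantiates the window nightly (the instance anchored
to night *d* ends at *d* + TSP WT and starts one window-length
earlier). A log is primary iff it lasts ≥ 60 min and (a) overlaps some
nightly window by > 0 min — it is anchored to the window of maximal
overlap, earlier night on ties — or (b) ends within 60 min (inclusive)
before the start of the earliest window-overlapping log of a night.
Clause (b) is interpretive: because reconstruction guarantees inter-log
gaps ≥ 60 min, reading "ends within 1 h of sleep occurring during the
typical period" as rescuing logs shortly *before* the window is the
only non-vacuous reading, and it fires exactly at 60 min gaps.
Primary logs sharing a night are **stitched** into one primary sleep
period; the gaps between consecutive components are imputed as wake.
A period whose components mix staged and unstaged families is flagged
`hybrid_stitched`, since its stage totals underestimate the night.

Night anchoring: a stitched period belongs to the calendar date of its
end (the wake date), matching the calendar rule's end-date convention
so per-day count differences compare aligned days.

## Metric conventions

With TATS = waketime − bedtime of the period and TST = summed
sleep-level minutes: total wake = TATS − TST exactly (integer-second
arithmetic); WASO = within-log wake minutes after the first sleep-level
segment plus all imputed gap minutes (pre-onset wake is excluded;
`restless` counts as wake); NWAK = within-log wake episodes after onset
plus the number of imputed gaps; efficiency = 100·TST/TATS, reported
missing (with a warning) when TST = 0. Stage minutes are summed over
staged segments and reported missing for periods with none. These
conventions follow standard sleep-medicine usage; each is a documented
choice where the upstream definitions are not public, and `restless`
handling is overridable. Days with no primary sleep yield no metrics
row (missing, not zero) to distinguish non-wear from sleeplessness.

Nonprimary (nap) accounting sums TST and counts over nonprimary logs
per calendar day of log end, reporting zeros on active days without
naps so per-day means are unbiased.

The sufficiency filter excludes a person iff the fraction of monitored
days (days with any recorded sleep) with under 4 h of total recorded
sleep strictly exceeds 30%; a person at exactly 30% is retained.

## Variation statistic and comparison

`delta_bar` is the mean over monitored days of the per-day difference
in primary-log counts (TSP − calendar). The denominator *n* counts
calendar days with at least one sleep log under either algorithm's day
anchoring (a `span_days` option uses the full span instead). An exact
identity follows from the 2×2 bookkeeping: `delta_bar · n = B − C`,
the stitched-cell count minus the cleaned-cell count for that person.

Stratification: data-driven quartiles use type-7 sample quantiles with
ties to the lower bin (the quantile type is a documented choice), or
fixed bands — net cleaning (< 0), modest (0–0.05), net stitching
(> 0.05). Paired comparison computes per-person metric means under each
algorithm first, then per-stratum medians/IQRs of the per-person
differences and a Wilcoxon signed-rank test (scipy); all-zero
differences report p = 1 by convention, and strata with fewer than two
paired persons report missing statistics. Mixed-effects modelling is
deliberately out of scope: the pipeline emits a tidy long table
(person, night, algorithm, metric, value, stratum) that any stats
environment can fit directly.

## Synthetic cohort generator

The simulator emulates the *structural* features the classifiers are
sensitive to, not sleep physiology: habitual bed/wake clock times with
Gaussian jitter (SD 25 min), nights crossing midnight, missing wear
days (5%), within-log wake interruptions longer than 3 minutes
(Poisson-thinned, 4–30 min), daytime naps inside an archetype-specific
window, staged level runs (cycling light/deep/light/REM with plausible
run lengths) only on logs ≥ 3 h, and — centrally — fragmented nights:
with probability `p_fragment` a night's wake gap (lognormal, median
90 min, truncated at the 60 min reconstruction threshold) is carved out
of the in-bed span at a uniform split point, leaving two logs of
≥ 60 min each, so a disrupted night still starts near habitual bedtime
and ends near habitual wake time with less sleep in between. Archetype
defaults: regular sleepers 23:00–07:00; fragmented insomnia 22:30–06:30
with more wake bouts; shift workers 08:00–13:00 with a 17:00–19:00 nap
window; nappers with frequent early-afternoon naps. Profiles whose nap
window intersects the habitual sleep window are rejected as infeasible
(the ground truth would be ill-defined).

Ground truth records each emitted log's night and primary/nap status.
What passing tests show: the user-centric classifier recovers the
designed labels at least as well as the calendar rule for every
archetype and strictly better under fragmentation, with the expected
sign pattern on every metric difference. What they cannot show:
performance against polysomnography, real staging quality, sensor
artifacts, or schedules with no regularity at all — on a person whose
*every* night is fragmented at a random position, the derived window
itself is estimated from fragments, so a minority of fragments still
evade it (label accuracy ~0.9 rather than 1.0); this mirrors the
method's stated reliance on some schedule regularity.

## Numerical and scale choices

Circular medians are evaluated exactly at data points (the objective is
piecewise linear, so this attains the global minimum; verified against
a 1-minute grid scan in tests). All randomness flows through
`numpy.random.Generator` seeded per run; pipeline outputs are
byte-identical across reruns. Test and demonstration cohorts use
40–60 persons × 30–60 nights, sizes at which every cohort-level
property under test (equivalence on regular sleepers, ≥95% direction
recovery, conservation identities on > 1000 nights) is already stable.

Known limitations: polyphasic and rotating-shift schedules are outside
the design (one typical window per person); the imputed gap wake cannot
distinguish attempted sleep from purposeful activity; a static TSP may
lag slow schedule drift over multi-year monitoring (the rolling-window
option mitigates but is off by default); and the rescue clause is a
boundary rule that only ever fires at exactly 60-minute gaps.
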