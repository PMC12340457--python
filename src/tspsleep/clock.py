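"""Circular arithmetic for clock times on the 24 h circle.

Clock times are minutes since midnight on the circle ``[0, 1440)``, so
the distance between 23:30 and 00:30 is 60 minutes, not 1380. Habitual
bed/wake times and midsleep points are circular quantities: a cohort of
sleepers with midsleep points straddling midnight must not produce a
noon-ish "average" the way a naive linear median would.
"""

from __future__ import annotations

from datetime import datetime, time
from typing import Sequence

import numpy as np

DAY_MIN = 1440.0

#: anchor for deterministic tie-breaking when a circular median is not
#: unique: the earliest minimizer on the clockwise arc starting at 18:00
#: (a conventional "evening origin" that precedes typical bedtimes).
TIE_ANCHOR_MIN = 18 * 60.0


def clock_minutes(ts: datetime) -> float:
    """Minutes since local midnight of a timestamp."""
    return ts.hour * 60.0 + ts.minute + ts.second / 60.0


def wrap(minutes: float) -> float:
    return float(np.mod(minutes, DAY_MIN))


def circ_dist(a: float, b: float) -> float:
    """Shortest arc length between two clock times, in minutes (<= 720)."""
    d = abs(wrap(a) - wrap(b))
    return min(d, DAY_MIN - d)


def forward_arc(a: float, b: float) -> float:
    """Clockwise arc length from ``a`` to ``b`` in ``[0, 1440)``."""
    return wrap(b - a)


def circ_median(values: Sequence[float]) -> float:
    """Circular median of clock times.

    Returns the clock time minimizing the summed shortest-arc distances
    to ``values``. The minimum of this piecewise-linear objective is
    attained at one of the data points (or on a flat arc between two of
    them); ties are broken by taking the earliest minimizer on the
    clockwise arc from 18:00, so results are deterministic.
    """
    vals = np.mod(np.asarray(values, dtype=float), DAY_MIN)
    if vals.size == 0:
        raise ValueError("circ_median of empty sequence")
    # evaluate the objective at every data point
    diff = np.abs(vals[:, None] - vals[None, :])
    dist = np.minimum(diff, DAY_MIN - diff)
    costs = dist.sum(axis=0)
    best = costs.min()
    minimizers = vals[np.isclose(costs, best)]
    offsets = np.mod(minimizers - TIE_ANCHOR_MIN, DAY_MIN)
    return float(minimizers[np.argmin(offsets)])


def to_time(minutes: float) -> time:
    m = wrap(minutes)
    h, rem = divmod(int(round(m * 60)), 3600)
    mi, s = divmod(rem, 60)
    return time(h % 24, mi, s)
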