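"""Variation-from-typical statistic and algorithm comparison.

For each person, the variation score is the mean over monitored days of
the signed difference in the number of primary sleep logs assigned by
the user-centric (TSP) versus calendar-relative (isMainSleep)
algorithms:

    delta_bar = (1/n) * sum_i [ SL_tsp(i) − SL_ismain(i) ]

A positive score means disjointed night sleep was *stitched* (fragmented
sleepers); a negative score means misassigned daytime sleep was
*cleaned*; zero means the calendar assumption already fit. The cohort is
stratified either into data-driven quartiles of the score or into three
fixed bands (< 0 net cleaning, 0–0.05 modest, > 0.05 net stitching).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedLog
from .metrics import METRIC_COLUMNS

MODEST_UPPER = 0.05


@dataclass
class VariationScore:
    person_id: str
    delta_bar: float
    n_days: int
    quartile: Optional[int] = None
    category3: Optional[str] = None


@dataclass
class ReclassSummary:
    """Counts of the four reclassification cells over a cohort."""

    a_no_change_primary: int
    b_stitched: int
    c_cleaned: int
    d_no_change_nonprimary: int

    @property
    def total(self) -> int:
        return (self.a_no_change_primary + self.b_stitched
                + self.c_cleaned + self.d_no_change_nonprimary)

    def as_frame(self) -> pd.DataFrame:
        counts = {
            "A_no_change_primary": self.a_no_change_primary,
            "B_stitched": self.b_stitched,
            "C_cleaned": self.c_cleaned,
            "D_no_change_nonprimary": self.d_no_change_nonprimary,
        }
        total = max(self.total, 1)
        return pd.DataFrame({
            "category": list(counts),
            "n_logs": list(counts.values()),
            "pct": [100.0 * v / total for v in counts.values()],
        })


def _daily_primary_counts(classified: Sequence[ClassifiedLog],
                          algorithm: str) -> dict:
    counts: dict = {}
    for cl in classified:
        if cl.is_primary(algorithm):
            d = cl.night_date(algorithm)
            counts[d] = counts.get(d, 0) + 1
    return counts


def variation_score(person_labels: Sequence[ClassifiedLog],
                    denominator: str = "active_days") -> VariationScore:
    """Per-person mean nightly change in primary-log counts (TSP − isMainSleep).

    ``denominator`` chooses n: ``active_days`` counts calendar days with
    at least one sleep log under either algorithm's day anchoring;
    ``span_days`` uses the full monitoring span.
    """
    if not person_labels:
        raise ValueError("no labeled logs for this person")
    tsp_counts = _daily_primary_counts(person_labels, "tsp")
    ismain_counts = _daily_primary_counts(person_labels, "ismain")
    active = set(tsp_counts) | set(ismain_counts)
    active |= {cl.night_date("ismain") for cl in person_labels}
    if denominator == "active_days":
        n = len(active)
    elif denominator == "span_days":
        n = (max(active) - min(active)).days + 1
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    total = sum(tsp_counts.get(d, 0) - ismain_counts.get(d, 0) for d in active)
    return VariationScore(person_labels[0].person_id, total / n, n)


def reclass_summary(all_labels: Sequence[ClassifiedLog]) -> ReclassSummary:
    """Tabulate the 2x2 of (isMainSleep, TSP) labels over all logs."""
    cells = {"A": 0, "B": 0, "C": 0, "D": 0}
    for cl in all_labels:
        cells[cl.reclass_category] += 1
    return ReclassSummary(cells["A"], cells["B"], cells["C"], cells["D"])


def assign_strata(scores: Sequence[VariationScore],
                  mode: str = "quartile") -> list[VariationScore]:
    """Stratify variation scores into quartiles or three fixed bands.

    Quartiles use type-7 sample quantiles of ``delta_bar`` with ties
    assigned to the lower bin. The three-level bands are: net cleaning
    (< 0), modest (0 to 0.05 inclusive), net stitching (> 0.05).
    """
    scores = list(scores)
    if mode == "quartile":
        if len(scores) < 4:
            raise ValueError("quartile mode needs at least 4 persons")
        vals = np.array([s.delta_bar for s in scores])
        qs = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 (linear) default
        for s in scores:
            s.quartile = 1 + int(np.sum(s.delta_bar > qs))
    elif mode == "three_level":
        for s in scores:
            if s.delta_bar < 0:
                s.category3 = "net_cleaning"
            elif s.delta_bar <= MODEST_UPPER:
                s.category3 = "modest"
            else:
                s.category3 = "net_stitching"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return scores


def scores_frame(scores: Sequence[VariationScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores],
                        columns=["person_id", "delta_bar", "n_days",
                                 "quartile", "category3"])


def _person_means(nights: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in METRIC_COLUMNS if c in nights.columns]
    return nights.groupby("person_id")[cols].mean()


def paired_compare(nights_ismain: pd.DataFrame,
                   nights_tsp: pd.DataFrame,
                   strata: Optional[pd.Series] = None,
                   nonprimary_ismain: Optional[pd.DataFrame] = None,
                   nonprimary_tsp: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-stratum paired differences (TSP − isMainSleep) per metric.

    Per-person metric means are computed first under each algorithm;
    the cohort median and IQR of the per-person differences are reported
    together with a Wilcoxon signed-rank p value. With identical inputs
    every difference is 0 and p = 1 by convention; strata with fewer
    than two paired persons report missing statistics.

    ``strata`` maps person_id -> stratum label; omitted = one stratum.
    ``nonprimary_*`` frames add nonprimary_tst_min / nonprimary_count
    (per-person day means) to the compared metrics.
    """
    means_i = _person_means(nights_ismain)
    means_t = _person_means(nights_tsp)

    if nonprimary_ismain is not None and len(nonprimary_ismain):
        np_cols = ["nonprimary_tst_min", "nonprimary_count"]
        means_i = means_i.join(nonprimary_ismain.groupby("person_id")[np_cols].mean(),
                               how="left").fillna({c: 0.0 for c in np_cols})
        means_t = means_t.join(nonprimary_tsp.groupby("person_id")[np_cols].mean()
                               if nonprimary_tsp is not None and len(nonprimary_tsp)
                               else pd.DataFrame(columns=np_cols),
                               how="left").fillna({c: 0.0 for c in np_cols})

    common = means_i.index.intersection(means_t.index)
    diffs = (means_t.loc[common] - means_i.loc[common])
    if strata is None:
        strata = pd.Series("all", index=common)
    rows = []
    for stratum, idx in diffs.groupby(strata.reindex(common)).groups.items():
        sub = diffs.loc[idx]
        for metric in sub.columns:
            d = sub[metric].dropna().to_numpy()
            row = {"stratum": stratum, "metric": metric, "n_persons": len(d)}
            if len(d) < 2:
                row.update(median=np.nan, q1=np.nan, q3=np.nan, wilcoxon_p=np.nan)
            else:
                q1, med, q3 = np.percentile(d, [25, 50, 75])
                if np.allclose(d, 0.0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
                row.update(median=med, q1=q1, q3=q3, wilcoxon_p=p)
            rows.append(row)
    return pd.DataFrame(rows, columns=["stratum", "metric", "n_persons",
                                       "median", "q1", "q3", "wilcoxon_p"])


def long_table(nights: pd.DataFrame,
               strata: Optional[pd.Series] = None) -> pd.DataFrame:
    """Tidy (person, night, algorithm, metric, value, stratum) table.

    Ready for a downstream mixed-effects fit in any stats environment;
    no model is fit here.
    """
    cols = [c for c in METRIC_COLUMNS if c in nights.columns]
    out = nights.melt(id_vars=["person_id", "night_date", "algorithm"],
                      value_vars=cols, var_name="metric", value_name="value")
    if strata is not None:
        out["stratum"] = out["person_id"].map(strata)
    return out
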