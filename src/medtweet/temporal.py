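"""Temporal aggregation of tweet volume and a monthly-seasonality test.

Counts of tweets (or sums of likes/retweets) are aggregated per category
into yearly bins, calendar-month-of-year bins, or custom multi-year
periods (default: one three-year period 2009-2011 followed by two-year
periods through 2019). Proportions are taken against the grand total of
the grid.

Seasonality is tested with the tie-corrected Kruskal-Wallis H statistic:
groups are the 12 calendar months and each observation is one year's total
of the measure within that month, so an 11-year corpus contributes 12
groups of 11 observations. H is referred to a chi-square distribution with
k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .categorize import CategoryScheme, DEFAULT_SCHEME, assign_categories
from .corpus_io import TweetRecord

__all__ = [
    "TimeBinSpec",
    "DEFAULT_PERIODS",
    "KruskalWallisResult",
    "aggregate_counts",
    "period_proportions",
    "kruskal_wallis",
    "monthly_seasonality_test",
]

#: Default custom periods: one 3-year bin then four 2-year bins.
DEFAULT_PERIODS: tuple[tuple[int, int], ...] = (
    (2009, 2011),
    (2012, 2013),
    (2014, 2015),
    (2016, 2017),
    (2018, 2019),
)

_MEASURES = ("tweets", "retweets", "likes")


@dataclass(frozen=True)
class TimeBinSpec:
    """How to bin tweets in time.

    ``unit`` is one of ``year`` (one bin per calendar year in
    [year_start, year_end]), ``month_of_year`` (12 bins, pooling years), or
    ``custom_periods`` (inclusive year ranges, non-overlapping and ordered).
    """

    unit: str = "year"
    year_start: int = 2009
    year_end: int = 2019
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS

    def __post_init__(self) -> None:
        if self.unit not in ("year", "month_of_year", "custom_periods"):
            raise ValueError(f"unknown time unit {self.unit!r}")
        if self.year_start > self.year_end:
            raise ValueError("year_start must be <= year_end")
        if self.unit == "custom_periods":
            prev_end = None
            for start, end in self.periods:
                if start > end:
                    raise ValueError(f"invalid period {start}-{end}")
                if prev_end is not None and start <= prev_end:
                    raise ValueError("periods must be ordered and non-overlapping")
                prev_end = end

    def labels(self) -> list[str]:
        if self.unit == "year":
            return [str(y) for y in range(self.year_start, self.year_end + 1)]
        if self.unit == "month_of_year":
            return [f"{m:02d}" for m in range(1, 13)]
        return [f"{s}-{e}" for s, e in self.periods]

    def label_for(self, tweet: TweetRecord) -> str:
        d = tweet.posted_date
        if self.unit == "year":
            if not self.year_start <= d.year <= self.year_end:
                raise ValueError(
                    f"tweet {tweet.tweet_id} dated {d} outside bin coverage "
                    f"{self.year_start}-{self.year_end}"
                )
            return str(d.year)
        if self.unit == "month_of_year":
            return f"{d.month:02d}"
        for start, end in self.periods:
            if start <= d.year <= end:
                return f"{start}-{end}"
        raise ValueError(
            f"tweet {tweet.tweet_id} dated {d} outside the configured periods"
        )


@dataclass(frozen=True)
class KruskalWallisResult:
    """Tie-corrected H statistic, df = k-1, chi-square upper-tail p."""

    H: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


def _measure_value(tweet: TweetRecord, measure: str) -> int:
    if measure == "tweets":
        return 1
    if measure == "retweets":
        return tweet.retweets
    if measure == "likes":
        return tweet.likes
    raise ValueError(f"unknown measure {measure!r}")


def aggregate_counts(
    corpus: Sequence[TweetRecord],
    scheme: CategoryScheme = DEFAULT_SCHEME,
    spec: TimeBinSpec = TimeBinSpec(),
    measure: str = "tweets",
) -> pd.DataFrame:
    """Bin x category grid of counts; empty cells are explicit zeros.

    A tweet matching several categories contributes to each matching
    column. Dates outside the spec's coverage are a hard error.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    grid = pd.DataFrame(
        0, index=pd.Index(spec.labels(), name="bin"), columns=scheme.names,
        dtype=np.int64,
    )
    for tweet in corpus:
        label = spec.label_for(tweet)
        value = _measure_value(tweet, measure)
        for cat in assign_categories(tweet, scheme):
            grid.loc[label, cat] += value
    return grid


def period_proportions(grid: pd.DataFrame) -> pd.DataFrame:
    """Each cell as a percentage of the grid's grand total."""
    total = int(grid.to_numpy().sum())
    if total == 0:
        raise ValueError("cannot take proportions of an all-zero grid")
    return grid.astype(float) / total * 100.0


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H test across >=2 non-empty groups.

    If every pooled observation is identical the statistic is 0 and p = 1
    (the tie correction is degenerate there). The chi-square approximation
    is used for the p-value regardless of group sizes.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    sizes = tuple(len(g) for g in groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(0.0, df, 1.0, sizes)
    H, p = stats.kruskal(*groups)
    return KruskalWallisResult(float(H), df, float(p), sizes)


def monthly_seasonality_test(
    corpus: Sequence[TweetRecord],
    measure: str = "tweets",
    scheme: CategoryScheme = DEFAULT_SCHEME,
    per_category: bool = False,
) -> KruskalWallisResult:
    """Test whether the measure's volume differs across calendar months.

    Groups are the 12 months; by default each observation is one year's
    pooled total of the measure for that month (zero-filled over the full
    span of years in the corpus). With ``per_category`` each (year,
    category) total is a separate observation.
    """
    if not corpus:
        raise ValueError("empty corpus")
    years = sorted({t.posted_date.year for t in corpus})
    if len(years) < 2:
        raise ValueError("corpus must span at least two calendar years")
    year_span = range(years[0], years[-1] + 1)

    if per_category:
        keys = [(y, c) for y in year_span for c in scheme.names]
        totals = {(m, k): 0 for m in range(1, 13) for k in keys}
        for tweet in corpus:
            d = tweet.posted_date
            value = _measure_value(tweet, measure)
            for cat in assign_categories(tweet, scheme):
                totals[(d.month, (d.year, cat))] += value
        groups = [
            [totals[(m, k)] for k in keys] for m in range(1, 13)
        ]
    else:
        totals = {(m, y): 0 for m in range(1, 13) for y in year_span}
        for tweet in corpus:
            d = tweet.posted_date
            totals[(d.month, d.year)] += _measure_value(tweet, measure)
        groups = [
            [totals[(m, y)] for y in year_span] for m in range(1, 13)
        ]
    return kruskal_wallis(groups)
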