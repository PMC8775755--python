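"""Per-category engagement summaries and the engagement odds ratio.

The summary table mirrors the study's result table: per category, the tweet
count, its percentage of the corpus total, like and retweet totals, and the
per-tweet like/retweet ratios.

The engagement odds ratio compares two categories' per-tweet event rates:

    OR = (events_a / trials_a) / (events_b / trials_b)

with a Wald-type confidence interval on the log scale,

    CI = exp( ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) )

where a = events_a, b = trials_a, c = events_b, d = trials_b and z is the
standard-normal quantile for the confidence level (1.96 at 95%). Note these
"odds" are rate ratios: likes and retweets are event counts that may exceed
the number of tweets, and no 2x2 contingency table is formed. This is the
statistic as the source analysis constructs it, kept deliberately rather
than replaced by textbook odds-ratio semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import exp, log, sqrt
from typing import Sequence

from scipy.stats import norm

from .categorize import CategoryScheme, DEFAULT_SCHEME, assign_categories
from .corpus_io import TweetRecord

__all__ = [
    "CategorySummary",
    "OddsRatioResult",
    "round_half_up",
    "summarize_categories",
    "engagement_odds_ratio",
    "or_panel",
]

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention), e.g. 2.735 -> 2.74."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategorySummary:
    """One summary-table row. Ratios are None for a category with no tweets.

    ``pct_tweets``, ``likes_per_tweet`` and ``retweets_per_tweet`` are stored
    unrounded; reports round to one decimal, half away from zero.
    """

    category: str
    n_tweets: int
    pct_tweets: float
    n_likes: int
    likes_per_tweet: float | None
    n_retweets: int
    retweets_per_tweet: float | None

    def rounded(self) -> tuple:
        """Row formatted to the report precision (one decimal)."""
        return (
            self.category,
            self.n_tweets,
            round_half_up(self.pct_tweets, 1),
            self.n_likes,
            None if self.likes_per_tweet is None else round_half_up(self.likes_per_tweet, 1),
            self.n_retweets,
            None if self.retweets_per_tweet is None else round_half_up(self.retweets_per_tweet, 1),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """An engagement odds ratio with its log-scale Wald CI (unrounded)."""

    category: str
    reference: str
    measure: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.odds_ratio, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def summarize_categories(
    corpus: Sequence[TweetRecord], scheme: CategoryScheme = DEFAULT_SCHEME
) -> tuple[list[CategorySummary], CategorySummary]:
    """Summarize an (already filtered) corpus per category, plus a totals row.

    A tweet matching several categories contributes to each matching row,
    while the totals row counts every distinct tweet exactly once, so the
    per-category counts are additive only when categories are disjoint.
    Percentages are taken against the grand (distinct-tweet) total.
    """
    grand_tweets = len(corpus)
    grand_likes = sum(t.likes for t in corpus)
    grand_retweets = sum(t.retweets for t in corpus)

    rows: list[CategorySummary] = []
    for name in scheme.names:
        members = [t for t in corpus if name in assign_categories(t, scheme)]
        n = len(members)
        likes = sum(t.likes for t in members)
        retweets = sum(t.retweets for t in members)
        rows.append(
            CategorySummary(
                category=name,
                n_tweets=n,
                pct_tweets=(100.0 * n / grand_tweets) if grand_tweets else 0.0,
                n_likes=likes,
                likes_per_tweet=(likes / n) if n else None,
                n_retweets=retweets,
                retweets_per_tweet=(retweets / n) if n else None,
            )
        )
    totals = CategorySummary(
        category="total",
        n_tweets=grand_tweets,
        pct_tweets=100.0 if grand_tweets else 0.0,
        n_likes=grand_likes,
        likes_per_tweet=None,
        n_retweets=grand_retweets,
        retweets_per_tweet=None,
    )
    return rows, totals


def engagement_odds_ratio(
    events_a: int,
    trials_a: int,
    events_b: int,
    trials_b: int,
    level: float = 0.95,
    category: str = "a",
    reference: str = "b",
    measure: str = "likes",
) -> OddsRatioResult:
    """Rate-ratio "odds" of engagement for group a relative to group b.

    All four counts must be strictly positive; the statistic and its
    variance term 1/a + 1/b + 1/c + 1/d are undefined at zero, and no
    continuity correction is applied.
    """
    counts = (events_a, trials_a, events_b, trials_b)
    if any(c <= 0 for c in counts):
        raise ValueError(
            f"odds undefined: all counts must be > 0, got {counts}"
        )
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    odds_ratio = (events_a / trials_a) / (events_b / trials_b)
    z = float(norm.ppf(0.5 + level / 2))
    se = sqrt(1 / events_a + 1 / trials_a + 1 / events_b + 1 / trials_b)
    return OddsRatioResult(
        category=category,
        reference=reference,
        measure=measure,
        odds_ratio=odds_ratio,
        ci_low=exp(log(odds_ratio) - z * se),
        ci_high=exp(log(odds_ratio) + z * se),
        level=level,
    )


def or_panel(
    summaries: Sequence[CategorySummary],
    reference: str,
    measure: str = "likes",
    level: float = 0.95,
) -> list[OddsRatioResult]:
    """One odds ratio per non-reference category against ``reference``.

    Input order is preserved; categories with zero tweets or zero events
    are skipped with a logged notice rather than silently corrected.
    """
    if measure not in ("likes", "retweets"):
        raise ValueError(f"measure must be 'likes' or 'retweets', got {measure!r}")
    by_name = {s.category: s for s in summaries}
    if reference not in by_name:
        raise ValueError(f"reference category {reference!r} not in summaries")
    ref = by_name[reference]
    ref_events = ref.n_likes if measure == "likes" else ref.n_retweets
    if ref.n_tweets == 0 or ref_events == 0:
        raise ValueError(
            f"reference category {reference!r} has zero counts for {measure}"
        )
    panel: list[OddsRatioResult] = []
    for summary in summaries:
        if summary.category == reference:
            continue
        events = summary.n_likes if measure == "likes" else summary.n_retweets
        if summary.n_tweets == 0 or events == 0:
            logger.info(
                "skipping category %r in OR panel: zero %s counts",
                summary.category,
                measure,
            )
            continue
        panel.append(
            engagement_odds_ratio(
                events,
                summary.n_tweets,
                ref_events,
                ref.n_tweets,
                level=level,
                category=summary.category,
                reference=reference,
                measure=measure,
            )
        )
    return panel
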