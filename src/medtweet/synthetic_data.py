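"""Seeded synthetic tweet corpora with exact per-category margins.

The generator emulates the structure of an outlet-curated food-group
corpus: eight disjoint hashtag categories, configurable per-category
tweet/like/retweet totals (defaults are the study's published per-category
margins: 1608 tweets, 123,363 likes, 48,946 retweets), posting dates over
2009-2019, 25 synthetic outlet accounts, and lexicon-built tweet text
hitting a target mean sentiment per category.

Engagement totals are allocated *exactly*: each category's like and
retweet totals are split across its tweets by a symmetric
Dirichlet-multinomial composition (concentration 1), so the summary table
over a generated corpus reproduces the configured margins as identities,
not in expectation. All randomness flows from a single integer seed;
identical configurations produce byte-identical JSONL.

What this corpus does NOT emulate: real tweet language, retweet cascades,
account-level posting styles, or any correlation between text content and
engagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Mapping

import numpy as np

from .corpus_io import TweetRecord
from .categorize import CategoryScheme, DEFAULT_SCHEME

__all__ = [
    "CategoryTarget",
    "GeneratorConfig",
    "DEFAULT_TARGETS",
    "MINI_LEXICON",
    "generate_corpus",
    "make_follower_table",
]

#: Bundled mini valence lexicon (AFINN-style integer valences, two words per
#: level so generated text has some variety). Swap in a full AFINN file for
#: real corpora; this one exists so generated text has known sentiment.
MINI_LEXICON: dict[str, int] = {
    "abysmal": -5, "horrific": -5,
    "dreadful": -4, "disastrous": -4,
    "awful": -3, "harmful": -3,
    "bland": -2, "poor": -2,
    "doubtful": -1, "dull": -1,
    "plain": 0, "ordinary": 0,
    "fair": 1, "decent": 1,
    "good": 2, "pleasant": 2,
    "great": 3, "tasty": 3,
    "excellent": 4, "wonderful": 4,
    "superb": 5, "outstanding": 5,
}

_WORDS_BY_VALENCE: dict[int, list[str]] = {}
for _w, _v in MINI_LEXICON.items():
    _WORDS_BY_VALENCE.setdefault(_v, []).append(_w)
for _v in _WORDS_BY_VALENCE:
    _WORDS_BY_VALENCE[_v].sort()

# Filler vocabulary; deliberately disjoint from MINI_LEXICON keys.
_FILLER = (
    "news", "report", "study", "update", "today", "weekly", "feature",
    "story", "coverage", "briefing", "notes", "review",
)


@dataclass(frozen=True)
class CategoryTarget:
    """Exact margins for one category: tweets, likes, retweets."""

    n_tweets: int
    n_likes: int
    n_retweets: int

    def __post_init__(self) -> None:
        if min(self.n_tweets, self.n_likes, self.n_retweets) < 0:
            raise ValueError("targets must be non-negative")
        if self.n_tweets == 0 and (self.n_likes or self.n_retweets):
            raise ValueError(
                "cannot allocate likes/retweets to a category with no tweets"
            )


#: Default margins: the published per-category tweet/like/retweet totals.
DEFAULT_TARGETS: dict[str, CategoryTarget] = {
    "red_meat": CategoryTarget(127, 11_710, 3_951),
    "red_wine": CategoryTarget(155, 11_680, 5_231),
    "soft_drinks": CategoryTarget(60, 2_786, 2_026),
    "dairy": CategoryTarget(723, 44_877, 19_590),
    "nuts": CategoryTarget(317, 27_327, 8_786),
    "olive_oil": CategoryTarget(31, 1_721, 1_205),
    "processed_meat": CategoryTarget(38, 3_337, 1_611),
    "mediterranean_diet": CategoryTarget(157, 19_925, 6_546),
}

_DEFAULT_ACCOUNTS = tuple(f"outlet{i:02d}" for i in range(1, 26))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic corpus.

    ``sentiment_targets`` are per-category mean scaled scores on the 0-100
    axis (default 50 = neutral everywhere, red wine 65 = positive, matching
    the qualitative sentiment pattern the generator is meant to emulate).
    ``seed`` is mandatory: it is the single source of randomness.
    """

    targets: Mapping[str, CategoryTarget] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    date_start: date = date(2009, 1, 1)
    date_end: date = date(2019, 12, 31)
    date_distribution: str = "uniform"
    yearly_weights: Mapping[int, float] | None = None
    accounts: tuple[str, ...] = _DEFAULT_ACCOUNTS
    sentiment_targets: Mapping[str, float] = field(
        default_factory=lambda: {"red_wine": 65.0}
    )
    default_sentiment: float = 50.0
    language: str = "en"
    seed: int = 0
    multi_category_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")
        if self.date_distribution not in ("uniform", "yearly_weights"):
            raise ValueError(
                f"unknown date distribution {self.date_distribution!r}"
            )
        if self.date_distribution == "yearly_weights":
            if not self.yearly_weights:
                raise ValueError("yearly_weights required for that distribution")
            total = sum(self.yearly_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"yearly weights must sum to 1, got {total}")
        if not 0.0 <= self.multi_category_rate <= 1.0:
            raise ValueError("multi_category_rate must be in [0, 1]")
        if not self.accounts:
            raise ValueError("at least one account is required")


def _sentiment_word_pair(target_scaled: float, rng: np.random.Generator) -> list[str]:
    """Two lexicon words whose mean valence maps exactly to the target score.

    The target mean valence v = (target - 50) / 10 is representable as the
    mean of two integer valences whenever 2v rounds within [-10, 10]; the
    nearest representable value is used otherwise.
    """
    v = (target_scaled - 50.0) / 10.0
    half_units = int(np.clip(round(2 * v), -10, 10))
    a = half_units // 2
    b = half_units - a
    return [
        _WORDS_BY_VALENCE[a][int(rng.integers(len(_WORDS_BY_VALENCE[a])))],
        _WORDS_BY_VALENCE[b][int(rng.integers(len(_WORDS_BY_VALENCE[b])))],
    ]


def _draw_dates(
    n: int, config: GeneratorConfig, rng: np.random.Generator
) -> list[date]:
    start, end = config.date_start, config.date_end
    if config.date_distribution == "uniform":
        span = (end - start).days + 1
        offsets = rng.integers(0, span, size=n)
        return [start + timedelta(days=int(o)) for o in offsets]
    years = sorted(config.yearly_weights)
    probs = np.array([config.yearly_weights[y] for y in years], dtype=float)
    chosen = rng.choice(len(years), size=n, p=probs)
    out: list[date] = []
    for idx in chosen:
        y = years[int(idx)]
        lo = max(start, date(y, 1, 1))
        hi = min(end, date(y, 12, 31))
        if lo > hi:
            raise ValueError(f"year {y} has weight but lies outside the window")
        out.append(lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1))))
    return out


def _split_total(total: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` into n non-negative parts (exact sum)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    probs = rng.dirichlet(np.ones(n))
    return rng.multinomial(total, probs).astype(np.int64)


def generate_corpus(
    config: GeneratorConfig, scheme: CategoryScheme = DEFAULT_SCHEME
) -> list[TweetRecord]:
    """Generate a corpus with exactly the configured per-category margins.

    Every tweet carries exactly one category hashtag (disjoint assignment)
    unless ``multi_category_rate`` > 0, in which case that fraction of
    tweets additionally carries a hashtag from another category — useful
    for stress-testing category accounting, but it breaks the additivity
    of per-category totals.
    """
    rng = np.random.default_rng(config.seed)
    records: list[TweetRecord] = []
    counter = 0
    category_names = [n for n in scheme.names if n in config.targets]
    extra_names = [n for n in config.targets if n not in scheme.names]
    if extra_names:
        raise ValueError(f"targets reference unknown categories: {extra_names}")

    for cat in category_names:
        target = config.targets[cat]
        n = target.n_tweets
        if n == 0:
            continue
        tokens = sorted(scheme.tokens(cat))
        sentiment = config.sentiment_targets.get(cat, config.default_sentiment)
        dates = _draw_dates(n, config, rng)
        likes = _split_total(target.n_likes, n, rng)
        retweets = _split_total(target.n_retweets, n, rng)
        token_idx = rng.integers(0, len(tokens), size=n)
        account_idx = rng.integers(0, len(config.accounts), size=n)
        for i in range(n):
            counter += 1
            token = tokens[int(token_idx[i])]
            words = _sentiment_word_pair(sentiment, rng)
            fillers = [
                _FILLER[int(j)]
                for j in rng.integers(0, len(_FILLER), size=int(rng.integers(2, 5)))
            ]
            text = f"{words[0]} {words[1]} " + " ".join(fillers) + f" #{token}"
            hashtags = {token}
            if config.multi_category_rate and rng.random() < config.multi_category_rate:
                others = [c for c in category_names if c != cat]
                if others:
                    other = others[int(rng.integers(len(others)))]
                    other_tokens = sorted(scheme.tokens(other))
                    hashtags.add(other_tokens[int(rng.integers(len(other_tokens)))])
            records.append(
                TweetRecord(
                    tweet_id=f"syn-{counter:06d}",
                    account=config.accounts[int(account_idx[i])],
                    posted_at=datetime(
                        dates[i].year, dates[i].month, dates[i].day,
                        tzinfo=timezone.utc,
                    ),
                    text=text,
                    hashtags=frozenset(hashtags),
                    likes=int(likes[i]),
                    retweets=int(retweets[i]),
                    language=config.language,
                )
            )
    return records


def make_follower_table(config: GeneratorConfig) -> dict[str, int]:
    """Deterministic synthetic follower counts for the configured accounts.

    Counts are drawn log-normally around a few million followers — the
    scale of major-outlet Twitter audiences — from the config seed, so the
    same config always yields the same table.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    counts = np.exp(rng.normal(np.log(3e6), 1.0, size=len(config.accounts)))
    return {
        handle: int(c) for handle, c in zip(config.accounts, counts)
    }
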