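"""Lexicon-based tweet sentiment on a 0-100 scale with five bands.

Each tweet is tokenized and matched against an AFINN-style valence lexicon
(integer valences in [-5, +5]; multi-word entries are matched greedily
before single words). The mean valence of the matched terms is mapped
affinely onto a 0-100 axis,

    scaled = clamp(50 + 10 * mean_valence, 0, 100),

so that -5 maps to 0, 0 to the neutral midpoint 50, and +5 to 100. Tweets
with no lexicon matches score the neutral 50 and are included in category
means. The scaled axis is banded into five sentiment categories:
very negative [0-20], negative (20-40], neutral (40-60], positive (60-80],
very positive (80-100].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .corpus_io import TweetRecord
from .textproc import tokenize

__all__ = [
    "SentimentScore",
    "SentimentCategory",
    "score_tweet",
    "score_category",
    "classify_sentiment",
]

NEUTRAL_SCALED = 50.0


class SentimentCategory(str, Enum):
    VERY_NEGATIVE = "very_negative"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"
    VERY_POSITIVE = "very_positive"


@dataclass(frozen=True)
class SentimentScore:
    """Sentiment of one tweet: raw mean valence, 0-100 scaled score, match count."""

    raw_mean_valence: float | None
    scaled: float
    n_matched_terms: int


def _match_terms(tokens: list[str], lexicon: Mapping[str, int]) -> list[int]:
    """Valences of lexicon terms found in the token stream.

    Multi-word entries are matched greedily (longest span first); matched
    tokens are consumed and cannot contribute to a second match.
    """
    max_span = max((term.count(" ") + 1 for term in lexicon), default=1)
    valences: list[int] = []
    i = 0
    while i < len(tokens):
        matched_span = 0
        for span in range(min(max_span, len(tokens) - i), 0, -1):
            candidate = " ".join(tokens[i : i + span])
            if candidate in lexicon:
                valences.append(lexicon[candidate])
                matched_span = span
                break
        i += matched_span if matched_span else 1
    return valences


def score_tweet(text: str, lexicon: Mapping[str, int]) -> SentimentScore:
    """Score one tweet; unmatched text yields the neutral score 50."""
    valences = _match_terms(tokenize(text), lexicon)
    if not valences:
        return SentimentScore(None, NEUTRAL_SCALED, 0)
    mean_valence = sum(valences) / len(valences)
    scaled = min(100.0, max(0.0, 50.0 + 10.0 * mean_valence))
    return SentimentScore(mean_valence, scaled, len(valences))


def score_category(
    tweets: Sequence[TweetRecord], lexicon: Mapping[str, int]
) -> float:
    """Unweighted mean of per-tweet scaled scores over a category's tweets.

    No-match tweets participate at the neutral 50.
    """
    if not tweets:
        raise ValueError("cannot score an empty category")
    return sum(score_tweet(t.text, lexicon).scaled for t in tweets) / len(tweets)


def classify_sentiment(score: float) -> SentimentCategory:
    """Band a 0-100 score; intervals above 20 are left-open, right-closed."""
    if not 0 <= score <= 100:
        raise ValueError(f"sentiment score {score} outside [0, 100]")
    if score <= 20:
        return SentimentCategory.VERY_NEGATIVE
    if score <= 40:
        return SentimentCategory.NEGATIVE
    if score <= 60:
        return SentimentCategory.NEUTRAL
    if score <= 80:
        return SentimentCategory.POSITIVE
    return SentimentCategory.VERY_POSITIVE
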