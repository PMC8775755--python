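from datetime import datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from medtweet.corpus_io import TweetRecord
from medtweet.synthetic_data import GeneratorConfig, generate_corpus

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_tweet(
    tweet_id="t1",
    account="outlet01",
    when="2015-06-01T00:00:00+00:00",
    text="",
    hashtags=("dairy",),
    likes=0,
    retweets=0,
    **kwargs,
):
    """Terse TweetRecord builder for toy corpora."""
    return TweetRecord(
        tweet_id=tweet_id,
        account=account,
        posted_at=datetime.fromisoformat(when).astimezone(timezone.utc),
        text=text,
        hashtags=frozenset(hashtags),
        likes=likes,
        retweets=retweets,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_corpus():
    """Default-condition synthetic corpus (published per-category margins)."""
    return generate_corpus(GeneratorConfig(seed=7))
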