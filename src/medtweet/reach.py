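"""Potential reach: the potential audience of a hashtag or category.

Reach is the sum of follower counts over the *distinct* accounts that
posted at least one tweet in the subset — an account is counted once no
matter how many tweets it contributed. Follower counts come from a
snapshot follower table keyed by account handle; any per-tweet follower
field on the records is deliberately ignored here, since reach is a single
additive total over the whole study period.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .corpus_io import TweetRecord

__all__ = ["potential_reach", "MissingAccountError"]


class MissingAccountError(KeyError):
    """An account in the corpus subset is absent from the follower table."""

    def __init__(self, handles: list[str]):
        self.handles = handles
        super().__init__(
            f"accounts missing from follower table: {', '.join(handles)}"
        )


def potential_reach(
    tweets: Sequence[TweetRecord], followers: Mapping[str, int]
) -> int:
    """Sum of follower counts over distinct posting accounts (0 if empty)."""
    accounts = {t.account for t in tweets}
    missing = sorted(a for a in accounts if a not in followers)
    if missing:
        raise MissingAccountError(missing)
    return sum(followers[a] for a in accounts)
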