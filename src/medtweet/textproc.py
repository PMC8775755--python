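"""Low-level text utilities shared by the I/O, categorization and sentiment layers.

Hashtag canonicalization and tweet tokenization live here so that both the
corpus readers and the analysis modules agree on one definition of a token.
"""

from __future__ import annotations

import re

__all__ = ["normalize_hashtag", "extract_hashtags", "tokenize"]

_HASHTAG_RE = re.compile(r"#(\w+)", re.UNICODE)
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_WORD_SPLIT_RE = re.compile(r"\W+", re.UNICODE)


def normalize_hashtag(raw: str) -> str:
    """Canonicalize a hashtag: strip whitespace and a leading '#', lowercase.

    No other alteration is performed; internal characters are preserved.

    Raises
    ------
    ValueError
        If the token is empty after normalization.
    """
    token = raw.strip().lstrip("#").lower()
    if not token:
        raise ValueError(f"hashtag {raw!r} is empty after normalization")
    if any(ch.isspace() for ch in token):
        raise ValueError(f"hashtag {raw!r} contains whitespace")
    return token


def extract_hashtags(text: str) -> set[str]:
    """Return the canonical hashtag tokens embedded in free text."""
    return {m.group(1).lower() for m in _HASHTAG_RE.finditer(text)}


def tokenize(text: str) -> list[str]:
    """Split tweet text into lowercase word tokens.

    URLs and @-mentions are dropped; hashtags are kept as plain words with
    the '#' stripped; everything else splits on non-word characters.
    """
    cleaned = _URL_RE.sub(" ", text)
    cleaned = _MENTION_RE.sub(" ", cleaned)
    cleaned = cleaned.replace("#", " ")
    return [t for t in _WORD_SPLIT_RE.split(cleaned.lower()) if t]
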