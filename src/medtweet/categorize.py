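"""Food-group category assignment and corpus inclusion/exclusion filtering.

Tweets are assigned to categories by exact hashtag-token matching against a
closed scheme of eight food groups (red meat, red wine, soft drinks, dairy,
nuts and wholegrains, olive oil, processed meat, and the Mediterranean diet
as a whole). Filtering applies the study's inclusion window (outlet
whitelist, 2009-2019 date window, English language, >=1 matching category)
and drops curated-out and low-content tweets, with a per-criterion audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

from .corpus_io import TweetRecord
from .textproc import normalize_hashtag  # re-exported: canonical token rule

__all__ = [
    "CategoryScheme",
    "DEFAULT_SCHEME",
    "FilterConfig",
    "FilterAudit",
    "FILTER_CRITERIA",
    "normalize_hashtag",
    "assign_categories",
    "apply_filters",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered mapping of category names to hashtag-token sets.

    Matching is exact-token only: a tweet belongs to every category whose
    token set intersects its hashtag set, and to none if no token matches.
    """

    categories: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        for name, tokens in self.categories:
            for tok in tokens:
                if tok != tok.lower() or "#" in tok:
                    raise ValueError(
                        f"category {name!r}: token {tok!r} is not canonical"
                    )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "CategoryScheme":
        return cls(
            tuple(
                (name, frozenset(normalize_hashtag(t) for t in tokens))
                for name, tokens in mapping.items()
            )
        )

    def to_mapping(self) -> dict[str, list[str]]:
        return {name: sorted(tokens) for name, tokens in self.categories}

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.categories]

    def tokens(self, category: str) -> frozenset[str]:
        for name, toks in self.categories:
            if name == category:
                return toks
        raise KeyError(category)

    def all_tokens(self) -> frozenset[str]:
        out: set[str] = set()
        for _, toks in self.categories:
            out |= toks
        return frozenset(out)


#: The study's eight-category scheme over its closed list of 17 hashtags.
DEFAULT_SCHEME = CategoryScheme.from_mapping(
    {
        "red_meat": {"redmeat"},
        "red_wine": {"redwine"},
        "soft_drinks": {"softdrinks"},
        "dairy": {"dairy"},
        "nuts": {
            "nuts",
            "almonds",
            "walnut",
            "hazelnuts",
            "omega3",
            "wholegraincereals",
        },
        "olive_oil": {"oliveoil", "extravirginoliveoil"},
        "processed_meat": {"processedmeat", "ultraprocessedfood", "ultraprocessed"},
        "mediterranean_diet": {"meddiet", "mediterraneandiet"},
    }
)


def assign_categories(tweet: TweetRecord, scheme: CategoryScheme) -> set[str]:
    """Categories whose token sets intersect the tweet's hashtags (maybe none)."""
    return {name for name, toks in scheme.categories if toks & tweet.hashtags}


#: Audit order: each removed record is attributed to its first failing criterion.
FILTER_CRITERIA = (
    "account",
    "date",
    "language",
    "category",
    "relevant",
    "hashtag_only",
    "picture_only",
)


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion/exclusion rules for a corpus.

    Defaults encode the study window: tweets from the whitelisted outlets
    (no whitelist means any account), posted 2009-01-01..2019-12-31, in
    English, carrying at least one scheme hashtag, curated as relevant, and
    not hashtag-only or picture-only.
    """

    date_start: date | None = date(2009, 1, 1)
    date_end: date | None = date(2019, 12, 31)
    allowed_accounts: frozenset[str] | None = None
    required_language: str | None = "en"
    require_relevant: bool = True
    drop_hashtag_only: bool = True
    drop_picture_only: bool = True

    def __post_init__(self) -> None:
        if (
            self.date_start is not None
            and self.date_end is not None
            and self.date_start > self.date_end
        ):
            raise ValueError("date_start must be <= date_end")


@dataclass
class FilterAudit:
    """Per-criterion removal counts; removed + retained == input size."""

    removed: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in FILTER_CRITERIA}
    )
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def _first_failure(
    tweet: TweetRecord, scheme: CategoryScheme, config: FilterConfig
) -> str | None:
    if config.allowed_accounts is not None and tweet.account not in config.allowed_accounts:
        return "account"
    if config.date_start is not None and tweet.posted_date < config.date_start:
        return "date"
    if config.date_end is not None and tweet.posted_date > config.date_end:
        return "date"
    if config.required_language is not None and tweet.language != config.required_language:
        return "language"
    if not assign_categories(tweet, scheme):
        return "category"
    if config.require_relevant and not tweet.relevant:
        return "relevant"
    if config.drop_hashtag_only and tweet.hashtag_only:
        return "hashtag_only"
    if config.drop_picture_only and tweet.picture_only:
        return "picture_only"
    return None


def apply_filters(
    corpus: Sequence[TweetRecord],
    scheme: CategoryScheme = DEFAULT_SCHEME,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[TweetRecord], FilterAudit]:
    """Apply every enabled criterion; return retained records and the audit.

    Retained records satisfy all criteria AND match at least one scheme
    category. Order of retained records is preserved; the operation is
    idempotent.
    """
    audit = FilterAudit()
    kept: list[TweetRecord] = []
    for tweet in corpus:
        failure = _first_failure(tweet, scheme, config)
        if failure is None:
            kept.append(tweet)
        else:
            audit.removed[failure] += 1
    audit.retained = len(kept)
    return kept, audit
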