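"""Reading and writing tweet corpora, sentiment lexicons and follower tables.

The canonical on-disk corpus dialect is JSON-lines: one object per line with
the field names of :class:`TweetRecord`. A CSV importer with a fixed header
is provided as a convenience for flat exports. Sentiment lexicons use the
AFINN two-column tab-separated format (term, integer valence in [-5, +5]);
follower tables are two-column CSV with the header ``account,followers``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from .textproc import extract_hashtags, normalize_hashtag

__all__ = [
    "TweetRecord",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "read_followers",
    "write_followers",
    "CSV_COLUMNS",
]

#: Column header of the CSV corpus dialect, in order.
CSV_COLUMNS = [
    "tweet_id",
    "account",
    "posted_at",
    "text",
    "hashtags",
    "likes",
    "retweets",
    "language",
    "relevant",
    "hashtag_only",
    "picture_only",
    "followers_at_post",
]


class CorpusFormatError(ValueError):
    """A corpus, lexicon or follower file violates its dialect contract."""


@dataclass(frozen=True)
class TweetRecord:
    """One tweet with its engagement counts, hashtags and curation flags.

    ``relevant`` stands in for the manual topical-relevance adjudication of
    the original curation workflow; ``hashtag_only`` and ``picture_only``
    mark low-content tweets that the filters drop by default.
    """

    tweet_id: str
    account: str
    posted_at: datetime
    text: str
    hashtags: frozenset[str]
    likes: int
    retweets: int
    language: str = "en"
    relevant: bool = True
    hashtag_only: bool = False
    picture_only: bool = False
    followers_at_post: int | None = None

    def __post_init__(self) -> None:
        if self.likes < 0 or self.retweets < 0:
            raise ValueError(
                f"tweet {self.tweet_id}: negative engagement counts"
            )
        if self.followers_at_post is not None and self.followers_at_post < 0:
            raise ValueError(f"tweet {self.tweet_id}: negative follower count")
        for tag in self.hashtags:
            if tag != tag.lower() or "#" in tag or any(c.isspace() for c in tag):
                raise ValueError(
                    f"tweet {self.tweet_id}: hashtag {tag!r} is not canonical"
                )
        if self.posted_at.tzinfo is None:
            object.__setattr__(
                self, "posted_at", self.posted_at.replace(tzinfo=timezone.utc)
            )

    @property
    def posted_date(self) -> date:
        return self.posted_at.astimezone(timezone.utc).date()


def _parse_timestamp(raw: str) -> datetime:
    """Accept ISO-8601 timestamps; bare dates mean 00:00 UTC."""
    dt = datetime.fromisoformat(raw)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


def _canonical_hashtags(listed: Iterable[str], text: str) -> frozenset[str]:
    tags = {normalize_hashtag(t) for t in listed if t.strip().lstrip("#")}
    return frozenset(tags | extract_hashtags(text))


def _record_from_mapping(obj: dict, lineno: int) -> TweetRecord:
    try:
        raw_tags = obj.get("hashtags", [])
        if isinstance(raw_tags, str):
            raw_tags = raw_tags.split()
        followers = obj.get("followers_at_post")
        if followers in ("", None):
            followers = None
        else:
            followers = int(followers)
        return TweetRecord(
            tweet_id=str(obj["tweet_id"]),
            account=str(obj["account"]).lstrip("@"),
            posted_at=_parse_timestamp(str(obj["posted_at"])),
            text=str(obj.get("text", "")),
            hashtags=_canonical_hashtags(raw_tags, str(obj.get("text", ""))),
            likes=int(obj["likes"]),
            retweets=int(obj["retweets"]),
            language=str(obj.get("language", "en")),
            relevant=_as_bool(obj.get("relevant", True)),
            hashtag_only=_as_bool(obj.get("hashtag_only", False)),
            picture_only=_as_bool(obj.get("picture_only", False)),
            followers_at_post=followers,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CorpusFormatError(f"line {lineno}: malformed record ({exc})") from exc


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no", ""):
            return False
        raise ValueError(f"not a boolean: {value!r}")
    return bool(value)


def read_corpus(path: str | Path, format: str = "jsonl") -> list[TweetRecord]:
    """Read a tweet corpus in file order.

    Hashtags are canonicalized on read and unioned with any hashtags embedded
    in the tweet text. Duplicate tweet ids and malformed lines are hard
    errors; no record is ever silently dropped.
    """
    path = Path(path)
    if format == "jsonl":
        records = []
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(
                        f"line {lineno}: invalid JSON ({exc})"
                    ) from exc
                records.append(_record_from_mapping(obj, lineno))
    elif format == "csv":
        records = []
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(CSV_COLUMNS[:7]) - set(reader.fieldnames or [])
            if missing:
                raise CorpusFormatError(
                    f"CSV header missing columns: {sorted(missing)}"
                )
            for lineno, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, lineno))
    else:
        raise CorpusFormatError(f"unknown corpus format: {format!r}")

    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.tweet_id] = seen.get(rec.tweet_id, 0) + 1
    dupes = sorted(tid for tid, n in seen.items() if n > 1)
    if dupes:
        raise CorpusFormatError(f"duplicate tweet_id values: {dupes}")
    return records


def _record_to_mapping(rec: TweetRecord) -> dict:
    return {
        "tweet_id": rec.tweet_id,
        "account": rec.account,
        "posted_at": rec.posted_at.astimezone(timezone.utc).isoformat(),
        "text": rec.text,
        "hashtags": sorted(rec.hashtags),
        "likes": rec.likes,
        "retweets": rec.retweets,
        "language": rec.language,
        "relevant": rec.relevant,
        "hashtag_only": rec.hashtag_only,
        "picture_only": rec.picture_only,
        "followers_at_post": rec.followers_at_post,
    }


def write_corpus(
    corpus: Sequence[TweetRecord], path: str | Path, format: str = "jsonl"
) -> None:
    """Write a corpus; the output round-trips through :func:`read_corpus`."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                fh.write(json.dumps(_record_to_mapping(rec), ensure_ascii=False))
                fh.write("\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for rec in corpus:
                row = _record_to_mapping(rec)
                row["hashtags"] = " ".join(sorted(rec.hashtags))
                row["relevant"] = str(rec.relevant).lower()
                row["hashtag_only"] = str(rec.hashtag_only).lower()
                row["picture_only"] = str(rec.picture_only).lower()
                if row["followers_at_post"] is None:
                    row["followers_at_post"] = ""
                writer.writerow(row)
    else:
        raise CorpusFormatError(f"unknown corpus format: {format!r}")


def read_lexicon(path: str | Path) -> dict[str, int]:
    """Read an AFINN-format valence lexicon (term TAB integer in [-5, +5]).

    Terms are lowercased on read and may contain spaces (multi-word entries).
    """
    lexicon: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"line {lineno}: expected 'term<TAB>valence'"
                )
            term = parts[0].strip().lower()
            try:
                valence = int(parts[1])
            except ValueError as exc:
                raise CorpusFormatError(
                    f"line {lineno}: valence {parts[1]!r} is not an integer"
                ) from exc
            if not -5 <= valence <= 5:
                raise CorpusFormatError(
                    f"line {lineno}: valence {valence} outside [-5, +5]"
                )
            if term in lexicon:
                raise CorpusFormatError(f"line {lineno}: duplicate term {term!r}")
            lexicon[term] = valence
    return lexicon


def write_lexicon(lexicon: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in sorted(lexicon):
            fh.write(f"{term}\t{lexicon[term]}\n")


def read_followers(path: str | Path) -> dict[str, int]:
    """Read a two-column ``account,followers`` CSV into a follower table."""
    table: dict[str, int] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or []) != {"account", "followers"}:
            raise CorpusFormatError(
                "follower table must have header 'account,followers'"
            )
        for lineno, row in enumerate(reader, start=2):
            account = row["account"].strip().lstrip("@")
            followers = int(row["followers"])
            if followers < 0:
                raise CorpusFormatError(f"line {lineno}: negative follower count")
            if account in table:
                raise CorpusFormatError(
                    f"line {lineno}: duplicate account {account!r}"
                )
            table[account] = followers
    return table


def write_followers(table: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["account", "followers"])
        for account in sorted(table):
            writer.writerow([account, table[account]])
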