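"""Tweet-stream and domain-catalog I/O.

Tweet streams are JSON-lines files, one tweet object per line, with ISO-8601
UTC timestamps. Domain catalogs are CSV files mapping registered domains to
a factual-reliability label (conspiracy / questionable / reliable) and a
five-point political-bias label, in the style of Media Bias/Fact Check.

URL handling reduces every URL to its *registered* domain (public-suffix
aware, so ``news.bbc.co.uk`` → ``bbc.co.uk``), because credibility labels
apply to registered domains, not to individual hosts. Matching against the
catalog is exact on the registered domain — never substring — which keeps
``cdc.gov`` distinct from look-alike hosts.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable
from urllib.parse import urlsplit

import numpy as np

logger = logging.getLogger(__name__)

RELIABILITY_VOCAB = frozenset({"conspiracy", "questionable", "reliable", "unknown"})
BIAS_VOCAB = frozenset(
    {"left", "left_center", "least", "right_center", "right", "unknown"}
)
UNRELIABLE = frozenset({"conspiracy", "questionable"})


class FormatError(ValueError):
    """A file violated the expected schema or closed vocabulary."""


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One tweet-like event.

    ``retweeted_user_id`` and ``retweeted_tweet_id`` are both set (for a
    retweet) or both ``None`` (for an original tweet).
    """

    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str
    lang: str = "en"
    urls: tuple[str, ...] = ()
    hashtags: tuple[str, ...] = ()
    retweeted_user_id: str | None = None
    retweeted_tweet_id: str | None = None

    def __post_init__(self) -> None:
        if (self.retweeted_user_id is None) != (self.retweeted_tweet_id is None):
            raise ValueError(
                "retweeted_user_id and retweeted_tweet_id must be both "
                "present or both absent"
            )
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")

    @property
    def is_retweet(self) -> bool:
        return self.retweeted_tweet_id is not None

    def to_json(self) -> str:
        obj = {
            "tweet_id": self.tweet_id,
            "user_id": self.user_id,
            "timestamp": self.timestamp.astimezone(timezone.utc).isoformat(),
            "text": self.text,
            "lang": self.lang,
            "urls": list(self.urls),
            "hashtags": list(self.hashtags),
        }
        if self.is_retweet:
            obj["retweeted_user_id"] = self.retweeted_user_id
            obj["retweeted_tweet_id"] = self.retweeted_tweet_id
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_obj(cls, obj: dict) -> "TweetRecord":
        ts = datetime.fromisoformat(obj["timestamp"])
        if ts.tzinfo is None:
            raise ValueError("naive timestamp")
        return cls(
            tweet_id=str(obj["tweet_id"]),
            user_id=str(obj["user_id"]),
            timestamp=ts.astimezone(timezone.utc),
            text=str(obj["text"]),
            lang=str(obj.get("lang", "en")),
            urls=tuple(obj.get("urls", ())),
            hashtags=tuple(h.lower().lstrip("#") for h in obj.get("hashtags", ())),
            retweeted_user_id=obj.get("retweeted_user_id"),
            retweeted_tweet_id=obj.get("retweeted_tweet_id"),
        )


@dataclass(frozen=True, slots=True)
class DomainRecord:
    domain: str
    reliability: str = "unknown"
    bias: str = "unknown"

    def __post_init__(self) -> None:
        if self.reliability not in RELIABILITY_VOCAB:
            raise ValueError(f"unknown reliability label: {self.reliability!r}")
        if self.bias not in BIAS_VOCAB:
            raise ValueError(f"unknown bias label: {self.bias!r}")


@dataclass(frozen=True)
class SourceGroup:
    """A named set of registered domains (conspiracy / questionable / random)."""

    name: str
    domains: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", frozenset(self.domains))

    def __len__(self) -> int:
        return len(self.domains)


# Common multi-part public suffixes; the registered domain is the label
# immediately left of the public suffix. A curated subset of the Mozilla
# public-suffix list covering the second-level country registries most
# likely to appear in news-domain catalogs.
_MULTIPART_SUFFIXES = frozenset(
    {
        "co.uk", "org.uk", "ac.uk", "gov.uk", "net.uk", "ltd.uk", "plc.uk",
        "me.uk", "com.au", "net.au", "org.au", "edu.au", "gov.au", "id.au",
        "co.nz", "net.nz", "org.nz", "govt.nz", "co.jp", "or.jp", "ne.jp",
        "ac.jp", "go.jp", "co.in", "net.in", "org.in", "gen.in", "firm.in",
        "co.za", "org.za", "web.za", "com.br", "net.br", "org.br", "gov.br",
        "com.mx", "org.mx", "gob.mx", "com.ar", "org.ar", "com.cn", "net.cn",
        "org.cn", "gov.cn", "com.tw", "org.tw", "com.hk", "org.hk", "com.sg",
        "org.sg", "co.kr", "or.kr", "com.tr", "org.tr", "co.il", "org.il",
        "ac.il", "gov.il", "com.my", "com.ph", "com.pk", "com.ng", "com.eg",
        "com.sa", "com.ua", "co.th", "or.th", "co.id", "or.id", "com.vn",
    }
)


def url_to_domain(url: str) -> str | None:
    """Reduce a URL (or bare host) to its lowercase registered domain.

    Strips scheme, credentials, port, path, query and fragment; collapses
    subdomains onto the registered (public-suffix-aware) domain; a leading
    ``www.`` never survives. Returns ``None`` for anything unparseable —
    never raises, so malformed URLs mid-stream degrade to "no match".
    """
    if not url or not isinstance(url, str):
        return None
    raw = url.strip().lower()
    if "://" in raw:
        host = urlsplit(raw).hostname
    else:
        # bare host, possibly with a path ("example.com/x") or port
        host = urlsplit("//" + raw).hostname
    if not host or "." not in host:
        return None
    host = host.strip(".")
    labels = host.split(".")
    if len(labels) < 2 or not all(labels):
        return None
    # reject hosts with characters outside hostname alphabet
    if not all(
        all(c.isalnum() or c == "-" for c in lab) for lab in labels
    ):
        return None
    if len(labels) >= 3 and ".".join(labels[-2:]) in _MULTIPART_SUFFIXES:
        return ".".join(labels[-3:])
    return ".".join(labels[-2:])


def write_tweets(records: Iterable[TweetRecord], path: str | Path) -> int:
    """Write records as JSON-lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
            n += 1
    return n


def read_tweets(path: str | Path) -> tuple[list[TweetRecord], int]:
    """Read a JSONL tweet stream; returns ``(records, n_skipped)``.

    Malformed lines (bad JSON, missing required fields, naive timestamps)
    are counted and skipped with a logged warning. If more than half the
    non-empty lines are malformed the file is rejected outright.
    """
    records: list[TweetRecord] = []
    skipped = 0
    total = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            total += 1
            try:
                obj = json.loads(line)
                rec = TweetRecord.from_obj(obj)
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping malformed line %d: %s", lineno, exc)
                continue
            records.append(rec)
    if total and skipped > total / 2:
        raise FormatError(
            f"{skipped}/{total} lines malformed — not a tweet JSONL stream?"
        )
    return records, skipped


def load_catalog(path: str | Path) -> dict[str, DomainRecord]:
    """Load a domain catalog CSV (header: domain,reliability,bias).

    Domain keys are normalized through :func:`url_to_domain`; duplicate
    domains resolve last-wins with a logged warning; labels outside the
    closed vocabularies raise :class:`FormatError` naming the row.
    """
    catalog: dict[str, DomainRecord] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"domain", "reliability", "bias"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"catalog must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            domain = url_to_domain(row["domain"])
            if domain is None:
                raise FormatError(f"row {i}: unparseable domain {row['domain']!r}")
            try:
                rec = DomainRecord(
                    domain=domain,
                    reliability=row["reliability"].strip().lower(),
                    bias=row["bias"].strip().lower(),
                )
            except ValueError as exc:
                raise FormatError(f"row {i} ({row['domain']}): {exc}") from exc
            if domain in catalog:
                logger.warning("duplicate catalog entry for %s (last wins)", domain)
            catalog[domain] = rec
    return catalog


def write_catalog(catalog: dict[str, DomainRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["domain", "reliability", "bias"])
        for domain in sorted(catalog):
            rec = catalog[domain]
            writer.writerow([rec.domain, rec.reliability, rec.bias])


def sample_random_sources(
    all_shared_domains: set[str],
    exclude: set[str],
    k: int,
    seed: int,
) -> SourceGroup:
    """Uniform sample (without replacement) of k shared domains as the
    random baseline group, disjoint from ``exclude`` (the unreliable lists).
    Deterministic for a given seed."""
    candidates = sorted(set(all_shared_domains) - set(exclude))
    if len(candidates) < k:
        raise ValueError(
            f"need {k} candidate domains but only {len(candidates)} remain "
            f"after excluding {len(exclude)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=k, replace=False) if k else []
    return SourceGroup("random", frozenset(str(d) for d in chosen))


def group_from_catalog(
    catalog: dict[str, DomainRecord], reliability: str, k: int | None = None
) -> SourceGroup:
    """The group of cataloged domains with the given reliability label;
    if k is given, the first k in sorted order (deterministic truncation)."""
    domains = sorted(d for d, r in catalog.items() if r.reliability == reliability)
    if k is not None:
        domains = domains[:k]
    return SourceGroup(reliability, frozenset(domains))
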