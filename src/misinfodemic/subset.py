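"""Misinformation subsetting, narrative keyword tagging, hashtag tables and
moving-average volume curves.

The misinformation subset keeps every tweet carrying at least one URL whose
registered domain is labelled conspiracy or questionable in the catalog.
Narratives are tagged with keyword filters; the built-in defaults cover the
three recurring COVID-19 misinformation narratives (hydroxychloroquine and
alternative medicine; US officials and agencies; prevention measures).

Keyword matching is token-boundary by default: a plain keyword must match a
whole token, a trailing ``*`` matches a token prefix, and multi-word
patterns must match consecutive tokens. A ``substring=True`` mode is
available for platform-style case-insensitive substring search (which would
also tag "protest" for the keyword "test" — hence not the default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from ._text import tokenize
from .io import TweetRecord, UNRELIABLE, url_to_domain

__all__ = [
    "NarrativeSpec", "DEFAULT_NARRATIVES", "VolumeSeries",
    "misinfo_subset", "tag_narratives", "top_hashtags", "volume_curve",
]


@dataclass(frozen=True)
class NarrativeSpec:
    """A named narrative keyword filter; patterns are lowercase, a trailing
    '*' denotes token-prefix matching."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("patterns must be non-empty")
        for p in self.patterns:
            if not p or p != p.lower():
                raise ValueError(f"patterns must be lowercase and non-empty: {p!r}")


DEFAULT_NARRATIVES: tuple[NarrativeSpec, ...] = (
    NarrativeSpec("HCQ", ("hcq", "hydroxychloroquine")),
    NarrativeSpec("OFFICIALS", ("fauci", "brix", "cdc")),
    NarrativeSpec("PREVENTION", ("mask", "vaccine", "social distanc*", "test")),
)


@dataclass(frozen=True)
class VolumeSeries:
    """A binned count series with its trailing moving average."""

    label: str
    dates: tuple[date, ...]
    counts: tuple[int, ...]
    smoothed: tuple[float, ...]

    def __post_init__(self) -> None:
        if not len(self.dates) == len(self.counts) == len(self.smoothed):
            raise ValueError("dates, counts, smoothed must be equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "label": self.label,
             "count": self.counts, "smoothed": self.smoothed}
        )


def misinfo_subset(
    tweets: list[TweetRecord], catalog: dict
) -> tuple[list[TweetRecord], dict[str, int]]:
    """Tweets with >=1 URL from an unreliable (conspiracy/questionable)
    domain, order preserved; returns (kept, {"kept": k, "total": n})."""
    kept = []
    for tw in tweets:
        for url in tw.urls:
            dom = url_to_domain(url)
            if dom is not None and dom in catalog \
                    and catalog[dom].reliability in UNRELIABLE:
                kept.append(tw)
                break
    return kept, {"kept": len(kept), "total": len(tweets)}


def _match_token_patterns(tokens: list[str], pattern_tokens: list[str]) -> bool:
    """Consecutive-token match. A pattern token ending in '*' matches a
    token prefix; a plain pattern token matches the exact token or its
    naive plural (token + 's'), so "mask" tags "masks" while "test" still
    never tags "protest"."""
    m = len(pattern_tokens)
    if m == 0 or m > len(tokens):
        return False
    for i in range(len(tokens) - m + 1):
        ok = True
        for j, pat in enumerate(pattern_tokens):
            tok = tokens[i + j]
            if pat.endswith("*"):
                if not tok.startswith(pat[:-1]):
                    ok = False
                    break
            elif tok != pat and tok != pat + "s":
                ok = False
                break
        if ok:
            return True
    return False


def tag_narratives(
    tweet: TweetRecord | str,
    specs: tuple[NarrativeSpec, ...] = DEFAULT_NARRATIVES,
    substring: bool = False,
) -> set[str]:
    """The set of narrative names whose keyword filter matches the tweet
    text (a tweet can fall under several narratives)."""
    if not specs:
        raise ValueError("specs must be non-empty")
    text = tweet if isinstance(tweet, str) else tweet.text
    lowered = text.lower()
    tokens = tokenize(lowered)
    tags = set()
    for spec in specs:
        for pat in spec.patterns:
            if substring:
                if pat.rstrip("*") in lowered:
                    tags.add(spec.name)
                    break
            elif _match_token_patterns(tokens, pat.split()):
                tags.add(spec.name)
                break
    return tags


def top_hashtags(
    tweets: list[TweetRecord], n: int
) -> list[tuple[str, int]]:
    """Top-n hashtags by count (case-insensitive); ties broken
    lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = Counter()
    for tw in tweets:
        for tag in tw.hashtags:
            counts[tag.lower().lstrip("#")] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def _week_start(d: date) -> date:
    """Monday of d's ISO week."""
    return d - timedelta(days=d.weekday())


def trailing_mean(counts, window: int) -> np.ndarray:
    """Trailing moving average; the first window-1 entries average the
    available prefix."""
    s = pd.Series(counts, dtype=float)
    return s.rolling(window, min_periods=1).mean().to_numpy()


def volume_curve(
    tweets: list[TweetRecord],
    granularity: str = "day",
    window: int = 7,
    label: str = "volume",
) -> VolumeSeries:
    """Bin tweets by UTC day or ISO week (Monday-anchored) and smooth with a
    trailing moving average. Missing interior bins count 0."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if granularity not in ("day", "week"):
        raise ValueError("granularity must be 'day' or 'week'")
    if not tweets:
        return VolumeSeries(label, (), (), ())
    if granularity == "day":
        keys = [tw.timestamp.date() for tw in tweets]
        step = timedelta(days=1)
    else:
        keys = [_week_start(tw.timestamp.date()) for tw in tweets]
        step = timedelta(weeks=1)
    counter = Counter(keys)
    lo, hi = min(counter), max(counter)
    dates = []
    d = lo
    while d <= hi:
        dates.append(d)
        d += step
    counts = [counter.get(d, 0) for d in dates]
    smoothed = trailing_mean(counts, window)
    return VolumeSeries(label, tuple(dates), tuple(counts),
                        tuple(float(x) for x in smoothed))
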