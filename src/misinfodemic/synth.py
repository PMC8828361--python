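"""Synthetic tweet-stream generator.

Emulates, at desk scale, the statistical structure the downstream analysis
assumes of a COVID-era tweet corpus: latent left/right user leans with
homophilous domain sharing, a subpopulation-wide propensity to share URLs
from unreliable (conspiracy / questionable) outlets, planted linear growth
in daily unreliable-URL volume, lean-assortative retweeting, hyperactive
never-retweeted bot accounts, and bursty two-word topics with Gaussian-bump
daily intensity. Ground truth (latent lean, bot flag, propensity) is
recoverable via :func:`truth_table`, so every downstream stage can be
validated against planted structure.

The domain universe has two tiers: a small catalog of labelled outlets
(conspiracy, questionable, reliable-left, reliable-right) and a much larger
pool of uncatalogued background domains standing in for the long tail of
the web. The long tail is what makes a random sample of shared domains a
sparse co-sharing baseline, as it is on the real platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .io import DomainRecord, TweetRecord

__all__ = ["BurstTopic", "SynthConfig", "generate_stream", "truth_table",
           "make_catalog", "background_domains"]


class ConfigError(ValueError):
    """Invalid synthetic-stream configuration."""


@dataclass(frozen=True)
class BurstTopic:
    """A bursty topic: its peak day, bump width, and signature bigrams."""

    peak_day: int
    width_days: float
    bigrams: tuple[str, ...]


_BACKGROUND_VOCAB = (
    "city hospital people health news study update numbers today state "
    "country government week report cases rise fall data chart doctors "
    "nurses schools travel economy jobs outbreak wave spread local global "
    "officials press briefing morning evening emergency response supplies "
    "shortage recovery patients"
).split()

_NARRATIVE_PHRASES = (
    "hydroxychloroquine cure", "hcq works", "fauci lied", "cdc report",
    "mask mandate", "vaccine rollout", "social distancing rules",
    "test shortage",
)

_HASHTAG_VOCAB = ("covid19", "coronavirus", "pandemic", "lockdown",
                  "stayhome", "health", "plandemic")
_HASHTAG_WEIGHTS = (0.30, 0.25, 0.15, 0.10, 0.08, 0.07, 0.05)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults are the reference study conditions.

    ``fidelity`` is the probability that a catalogued (bias-carrying) URL a
    user shares matches the user's latent lean; ``misinfo_propensity`` is
    the per-URL probability of drawing from an unreliable outlet group.
    ``trend_slope_*`` plant additional unreliable URLs per day on top of the
    propensity-driven base volume.
    """

    n_users: int = 300
    n_domains_per_group: int = 40
    n_background_domains: int = 12000
    n_days: int = 120
    base_rate: float = 1.0
    lean_mix: float = 0.5
    fidelity: float = 0.8
    misinfo_propensity: float = 0.3
    trend_slope_conspiracy: float = 0.0
    trend_slope_questionable: float = 0.0
    retweet_homophily: float = 0.8
    retweet_rate: float = 0.3
    political_share: float = 0.4
    narrative_rate: float = 0.15
    n_bot_users: int = 0
    bot_rate_multiplier: float = 12.0
    topic_bursts: tuple[BurstTopic, ...] = ()
    burst_amplitude: float = 30.0
    start: date = date(2020, 3, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "lean_mix": self.lean_mix,
            "misinfo_propensity": self.misinfo_propensity,
            "retweet_homophily": self.retweet_homophily,
            "retweet_rate": self.retweet_rate,
            "political_share": self.political_share,
            "narrative_rate": self.narrative_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        if not 0.5 <= self.fidelity <= 1.0:
            raise ConfigError(f"fidelity must be in [0.5,1], got {self.fidelity}")
        if self.n_days < 14:
            raise ConfigError(f"n_days must be >= 14, got {self.n_days}")
        for name in ("n_users", "n_domains_per_group", "n_background_domains",
                     "n_bot_users"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be positive")


def make_catalog(config: SynthConfig) -> dict[str, DomainRecord]:
    """The labelled outlet catalog for this configuration.

    Each group has ``n_domains_per_group`` domains; unreliable outlets carry
    a left/right bias too (alternating), so every catalogued share is a
    Bernoulli(fidelity) draw on matching the sharer's lean.
    """
    catalog: dict[str, DomainRecord] = {}
    n = config.n_domains_per_group
    for i in range(n):
        bias = "right" if i % 2 == 0 else "left"
        d = f"conspnews{i:03d}.com"
        catalog[d] = DomainRecord(d, "conspiracy", bias)
        d = f"questnews{i:03d}.com"
        catalog[d] = DomainRecord(d, "questionable", bias)
        d = f"leftpress{i:03d}.com"
        catalog[d] = DomainRecord(d, "reliable", "left")
        d = f"rightpress{i:03d}.com"
        catalog[d] = DomainRecord(d, "reliable", "right")
    return catalog


def background_domains(config: SynthConfig) -> list[str]:
    """Uncatalogued long-tail domains."""
    return [f"site{i:05d}.net" for i in range(config.n_background_domains)]


def _assign_users(config: SynthConfig) -> pd.DataFrame:
    """Latent user table; its RNG stream is independent of the tweet draws
    so the truth table can be rebuilt without regenerating the stream."""
    rng = np.random.default_rng([config.seed % (2**31), 17])
    n_total = config.n_users + config.n_bot_users
    leans = np.where(rng.random(n_total) < config.lean_mix, "right", "left")
    ids = [f"u{i:05d}" for i in range(config.n_users)] + [
        f"bot{i:03d}" for i in range(config.n_bot_users)
    ]
    is_bot = np.array([False] * config.n_users + [True] * config.n_bot_users,
                      dtype=bool)
    return pd.DataFrame(
        {
            "user_id": ids,
            "lean": leans,
            "is_bot": is_bot,
            "propensity": config.misinfo_propensity,
        }
    )


def truth_table(config: SynthConfig) -> pd.DataFrame:
    """Ground-truth latent labels (user_id, lean, is_bot, propensity) for the
    stream :func:`generate_stream` produces from the same config."""
    return _assign_users(config)


class _Generator:
    def __init__(self, config: SynthConfig):
        self.cfg = config
        self.rng = np.random.default_rng([config.seed % (2**31), 41])
        self.users = _assign_users(config)
        cat = make_catalog(config)
        n = config.n_domains_per_group
        self.pools: dict[tuple[str, str], list[str]] = {}
        for rel in ("conspiracy", "questionable"):
            for bias in ("left", "right"):
                self.pools[(rel, bias)] = sorted(
                    d for d, r in cat.items()
                    if r.reliability == rel and r.bias == bias
                )
        self.pools[("reliable", "left")] = [f"leftpress{i:03d}.com" for i in range(n)]
        self.pools[("reliable", "right")] = [f"rightpress{i:03d}.com" for i in range(n)]
        self.background = background_domains(config)
        self.lean_of = dict(zip(self.users.user_id, self.users.lean))
        self._next_id = 0
        # originals by (lean, non-bot) from *previous* days, retweet pool
        self.rt_pool: dict[str, list[TweetRecord]] = {"left": [], "right": []}

    def _tid(self) -> str:
        self._next_id += 1
        return f"t{self._next_id:08d}"

    def _draw_domain(self, lean: str, forced: str | None = None) -> str:
        rng, cfg = self.rng, self.cfg
        if forced is None:
            if rng.random() < cfg.misinfo_propensity:
                forced = "conspiracy" if rng.random() < 0.5 else "questionable"
        if forced is not None:
            bias = lean if rng.random() < cfg.fidelity else (
                "left" if lean == "right" else "right")
            pool = self.pools[(forced, bias)]
            if not pool:  # degenerate tiny catalogs
                pool = self.pools[(forced, lean)] or self.background
            return pool[rng.integers(len(pool))]
        if rng.random() < cfg.political_share:
            bias = lean if rng.random() < cfg.fidelity else (
                "left" if lean == "right" else "right")
            pool = self.pools[("reliable", bias)]
            return pool[rng.integers(len(pool))]
        return self.background[rng.integers(len(self.background))]

    def _text(self, phrase: str | None = None) -> str:
        rng = self.rng
        k = int(rng.integers(5, 10))
        idx = rng.integers(len(_BACKGROUND_VOCAB), size=k)
        tokens = [_BACKGROUND_VOCAB[i] for i in idx]
        if phrase is None and rng.random() < self.cfg.narrative_rate:
            phrase = _NARRATIVE_PHRASES[rng.integers(len(_NARRATIVE_PHRASES))]
        if phrase is not None:
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens[pos:pos] = phrase.split()
        return " ".join(tokens)

    def _hashtags(self) -> tuple[str, ...]:
        rng = self.rng
        k = int(rng.choice([0, 1, 2], p=[0.55, 0.35, 0.10]))
        if k == 0:
            return ()
        picks = rng.choice(len(_HASHTAG_VOCAB), size=k, p=_HASHTAG_WEIGHTS)
        return tuple(_HASHTAG_VOCAB[i] for i in picks)

    def _original(self, user_id: str, lean: str, phrase: str | None = None,
                  forced_domain: str | None = None,
                  n_urls: int | None = None) -> TweetRecord:
        rng = self.rng
        if n_urls is None:
            n_urls = int(rng.choice([0, 1, 2], p=[0.35, 0.45, 0.20]))
        urls = []
        for _ in range(n_urls):
            dom = forced_domain or self._draw_domain(lean)
            urls.append(f"https://{dom}/p/{int(rng.integers(1_000_000))}")
        return TweetRecord(
            tweet_id=self._tid(), user_id=user_id,
            timestamp=_EPOCH,  # placeholder; day/jitter assigned later
            text=self._text(phrase), urls=tuple(urls),
            hashtags=self._hashtags(),
        )

    def _retweet(self, user_id: str, lean: str) -> TweetRecord | None:
        rng, cfg = self.rng, self.cfg
        target_lean = lean if rng.random() < cfg.retweet_homophily else (
            "left" if lean == "right" else "right")
        pool = self.rt_pool[target_lean] or self.rt_pool[
            "left" if target_lean == "right" else "right"]
        if not pool:
            return None
        src = pool[rng.integers(len(pool))]
        if src.user_id == user_id:
            return None
        return TweetRecord(
            tweet_id=self._tid(), user_id=user_id,
            timestamp=_EPOCH, text=src.text, urls=src.urls,
            hashtags=src.hashtags,
            retweeted_user_id=src.user_id, retweeted_tweet_id=src.tweet_id,
        )

    def run(self) -> list[TweetRecord]:
        cfg, rng = self.cfg, self.rng
        out: list[TweetRecord] = []
        reg = self.users[~self.users.is_bot]
        regular = list(zip(reg.user_id.tolist(), reg.lean.tolist()))
        bot = self.users[self.users.is_bot]
        bots = list(zip(bot.user_id.tolist(), bot.lean.tolist()))
        for day in range(cfg.n_days):
            day_events: list[TweetRecord] = []
            new_originals: list[TweetRecord] = []
            counts = rng.poisson(cfg.base_rate, size=len(regular))
            for (uid, lean), c in zip(regular, counts):
                for _ in range(int(c)):
                    rec = None
                    if day > 0 and rng.random() < cfg.retweet_rate:
                        rec = self._retweet(uid, lean)
                    if rec is None:
                        rec = self._original(uid, lean)
                        new_originals.append(rec)
                    day_events.append(rec)
            # bots: hyperactive originals plus occasional retweets; never
            # themselves retweeted (their originals stay out of the pool)
            bot_counts = rng.poisson(
                cfg.bot_rate_multiplier * cfg.base_rate, size=len(bots))
            for (uid, lean), c in zip(bots, bot_counts):
                for _ in range(int(c)):
                    day_events.append(self._original(uid, lean))
                if day > 0 and rng.random() < 0.5:
                    rec = self._retweet(uid, lean)
                    if rec is not None:
                        day_events.append(rec)
            # planted linear growth in unreliable volume
            for rel, slope in (("conspiracy", cfg.trend_slope_conspiracy),
                               ("questionable", cfg.trend_slope_questionable)):
                if slope > 0 and len(regular):
                    extra = rng.poisson(slope * day)
                    for _ in range(int(extra)):
                        uid, lean = regular[int(rng.integers(len(regular)))]
                        bias = lean if rng.random() < cfg.fidelity else (
                            "left" if lean == "right" else "right")
                        pool = self.pools[(rel, bias)] or self.background
                        dom = pool[rng.integers(len(pool))]
                        # trend extras stay out of the retweet pool so the
                        # planted slope is not amplified by re-sharing
                        rec = self._original(uid, lean, forced_domain=dom,
                                             n_urls=1)
                        day_events.append(rec)
            # bursty topics, Gaussian-bump intensity
            for topic in cfg.topic_bursts:
                sigma = max(topic.width_days / 2.0, 0.5)
                lam = cfg.burst_amplitude * float(
                    np.exp(-0.5 * ((day - topic.peak_day) / sigma) ** 2))
                n_burst = rng.poisson(lam) if lam > 1e-9 and len(regular) else 0
                for _ in range(int(n_burst)):
                    uid, lean = regular[int(rng.integers(len(regular)))]
                    phrase = topic.bigrams[rng.integers(len(topic.bigrams))]
                    rec = self._original(uid, lean, phrase=phrase)
                    new_originals.append(rec)
                    day_events.append(rec)
            # assign timestamps: uniform within-day jitter, stable order
            base = datetime.combine(cfg.start + timedelta(days=day),
                                    datetime.min.time(), tzinfo=timezone.utc)
            jitter = rng.integers(0, 86400, size=len(day_events))
            order = np.argsort(jitter, kind="stable")
            stamped = {}
            for rank in order:
                ev = day_events[rank]
                stamped[ev.tweet_id] = replace(
                    ev, timestamp=base + timedelta(seconds=int(jitter[rank])))
            # retweets must point at earlier tweets: targets come only from
            # previous days' pools, so any within-day order is consistent
            out.extend(stamped[day_events[r].tweet_id] for r in order)
            for rec in new_originals:
                self.rt_pool[self.lean_of[rec.user_id]].append(
                    stamped[rec.tweet_id])
        return out


_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


def generate_stream(config: SynthConfig) -> list[TweetRecord]:
    """Generate the full synthetic stream, in nondecreasing timestamp order.

    Deterministic: identical config (incl. seed) gives a byte-identical
    JSONL serialization.
    """
    return _Generator(config).run()
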