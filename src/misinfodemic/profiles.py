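"""Per-user political lean and misinformation-engagement profiles.

A user's lean is the political bias (left, left_center, least, right_center,
right) of the majority of the catalogued domains they shared; exact ties are
broken uniformly at random with a seeded generator. Users are classified
only if they shared more than ``min_urls`` URLs (strictly more; default 5).
Sharing counts both original tweets and retweets — a retweet republishes the
URL. A user who shared at least one conspiracy or questionable domain is
flagged as having engaged with misinformation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TweetRecord, UNRELIABLE, url_to_domain
from .subset import DEFAULT_NARRATIVES, NarrativeSpec, tag_narratives

__all__ = ["BIAS_CLASSES", "build_profiles", "lean_recovery_report"]

BIAS_CLASSES = ("left", "left_center", "least", "right_center", "right")
UNCLASSIFIED = "unclassified"


def build_profiles(
    tweets: list[TweetRecord],
    catalog: dict,
    min_urls: int = 5,
    seed: int = 0,
    narrative_specs: tuple[NarrativeSpec, ...] = DEFAULT_NARRATIVES,
    cataloged_only: bool = False,
) -> pd.DataFrame:
    """Profile table: one row per user appearing in the stream.

    Columns: user_id, n_urls, the five bias counts, n_tweets (originals
    only), lean, misinfo_engaged, narratives (sorted '|'-joined tags).
    ``n_urls`` counts every shared URL that parses to a domain; with
    ``cataloged_only=True`` only catalogued domains count toward the
    classification threshold.
    """
    stats: dict[str, dict] = {}
    for tw in tweets:
        st = stats.setdefault(
            tw.user_id,
            {
                "n_urls": 0,
                "bias": dict.fromkeys(BIAS_CLASSES, 0),
                "misinfo": False,
                "narr": set(),
                "n_tweets": 0,
            },
        )
        if not tw.is_retweet:
            st["n_tweets"] += 1
        st["narr"] |= tag_narratives(tw, narrative_specs)
        for url in tw.urls:
            dom = url_to_domain(url)
            if dom is None:
                continue
            rec = catalog.get(dom)
            if cataloged_only and rec is None:
                continue
            st["n_urls"] += 1
            if rec is not None:
                if rec.reliability in UNRELIABLE:
                    st["misinfo"] = True
                if rec.bias in st["bias"]:
                    st["bias"][rec.bias] += 1

    rng = np.random.default_rng(seed)
    rows = []
    for uid in sorted(stats):
        st = stats[uid]
        bias = st["bias"]
        total_bias = sum(bias.values())
        if st["n_urls"] <= min_urls or total_bias == 0:
            lean = UNCLASSIFIED
        else:
            best = max(bias.values())
            tied = sorted(b for b in BIAS_CLASSES if bias[b] == best)
            # the RNG is consulted only on exact ties, so perturbing a
            # single count removes the randomness for that user
            lean = tied[0] if len(tied) == 1 else tied[
                int(rng.integers(len(tied)))]
        rows.append(
            {
                "user_id": uid,
                "n_urls": st["n_urls"],
                **bias,
                "n_tweets": st["n_tweets"],
                "lean": lean,
                "misinfo_engaged": st["misinfo"],
                "narratives": "|".join(sorted(st["narr"])),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["user_id", "n_urls", *BIAS_CLASSES, "n_tweets", "lean",
                 "misinfo_engaged", "narratives"],
    )


def lean_recovery_report(
    profiles: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Confusion counts of assigned vs latent lean among classified users.

    ``truth`` is the generator's table (user_id, lean, is_bot, ...). Users
    in the profiles but absent from the truth table are an error. Returns
    {"confusion": DataFrame, "accuracy": float, "n_classified": int}.
    """
    missing = set(profiles.user_id) - set(truth.user_id)
    if missing:
        raise ValueError(
            f"{len(missing)} profiled users missing from truth table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    merged = profiles.merge(
        truth[["user_id", "lean"]].rename(columns={"lean": "latent"}),
        on="user_id",
    )
    classified = merged[merged.lean != UNCLASSIFIED]
    confusion = pd.crosstab(classified.latent, classified.lean)
    n = len(classified)
    correct = int((classified.lean == classified.latent).sum())
    return {
        "confusion": confusion,
        "accuracy": correct / n if n else float("nan"),
        "n_classified": n,
    }
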