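"""End-to-end orchestration: one config, all stages, one summary.

Stages run in dependency order — ingest → misinformation subset → user
profiles → retweet network (prune, core, narrative overlap) → source groups
→ co-sharing density → daily counts and trend fits → bigram shape clusters
— and every artifact is written under the output directory together with a
machine-readable ``summary.json``. All randomness funnels through the
single config seed, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import cosharing, retweet, subset, temporal, trends
from .io import (group_from_catalog, load_catalog, read_tweets,
                 sample_random_sources, url_to_domain)
from .profiles import build_profiles

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""


@dataclass
class RunConfig:
    tweets_path: str
    catalog_path: str
    out_dir: str
    top_n_bigrams: int = 50_000
    shape_k: int = 11
    shape_window_days: int = 21
    burst_fraction: float = 0.5
    min_urls: int = 5
    core_k: int = 100
    group_size: int = 250
    day_window: int = 7
    week_window: int = 7
    bot_rate_quantile: float = 0.95
    run_shape_clustering: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        return cls(**obj)

    def validate(self) -> None:
        for p in (self.tweets_path, self.catalog_path):
            if not Path(p).exists():
                raise PipelineError(f"input path does not exist: {p}")
        if self.min_urls < 0 or self.core_k < 1 or self.group_size < 1:
            raise PipelineError("parameter out of range")


def round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places,
                                           rounding=ROUND_HALF_UP))


def language_shares(lang_counts: dict[str, int]) -> pd.DataFrame:
    """Counts and percentage share (half-up, 2 decimals) per language tag,
    sorted by descending count."""
    if any(c < 0 for c in lang_counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(lang_counts.values())
    if total == 0:
        raise ValueError("zero total count")
    rows = [
        {"lang": tag, "count": int(c),
         "percent": round_half_up(100.0 * c / total)}
        for tag, c in sorted(lang_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["lang", "count", "percent"])


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to
    ``<out_dir>/summary.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": config.seed, "stages": {}}
    stage = "ingest"
    try:
        t0 = time.time()
        tweets, skipped = read_tweets(config.tweets_path)
        catalog = load_catalog(config.catalog_path)
        langs = {}
        for tw in tweets:
            langs[tw.lang] = langs.get(tw.lang, 0) + 1
        shares = language_shares(langs)
        shares.to_csv(out / "language_shares.csv", index=False)
        summary["stages"]["ingest"] = {
            "n_tweets": len(tweets), "n_skipped": skipped,
            "n_catalog_domains": len(catalog),
            "language_shares": shares.to_dict("records"),
            "elapsed_s": round(time.time() - t0, 3),
        }
        logger.info("ingest: %d tweets, %d skipped", len(tweets), skipped)

        stage = "subset"
        t0 = time.time()
        mis, stats = subset.misinfo_subset(tweets, catalog)
        vol = subset.volume_curve(mis, "day", config.day_window,
                                  label="misinfo")
        frames = [vol.to_frame()]
        for spec in subset.DEFAULT_NARRATIVES:
            tagged = [tw for tw in mis
                      if spec.name in subset.tag_narratives(tw, (spec,))]
            frames.append(
                subset.volume_curve(tagged, "day", config.day_window,
                                    label=spec.name).to_frame())
        pd.concat(frames).to_csv(out / "volume_curves.csv", index=False)
        hashtags = subset.top_hashtags(mis, 20) if mis else []
        (out / "top_hashtags.json").write_text(
            json.dumps(hashtags, indent=2, sort_keys=True))
        summary["stages"]["subset"] = {
            **stats, "top_hashtags": hashtags[:5],
            "elapsed_s": round(time.time() - t0, 3),
        }

        stage = "profiles"
        t0 = time.time()
        prof = build_profiles(tweets, catalog, min_urls=config.min_urls,
                              seed=config.seed)
        prof.to_csv(out / "user_profiles.csv", index=False)
        lean_counts = prof.lean.value_counts().to_dict()
        summary["stages"]["profiles"] = {
            "n_users": len(prof),
            "n_misinfo_engaged": int(prof.misinfo_engaged.sum()),
            "lean_counts": {k: int(v) for k, v in sorted(lean_counts.items())},
            "elapsed_s": round(time.time() - t0, 3),
        }

        stage = "retweet_network"
        t0 = time.time()
        g = retweet.build_retweet_graph(tweets, prof)
        tw_counts = retweet.original_tweet_counts(tweets)
        if tw_counts:
            thresh = float(pd.Series(list(tw_counts.values()))
                           .quantile(config.bot_rate_quantile))
        else:
            thresh = float("inf")
        pruned, removed = retweet.prune_bots(g, tw_counts, thresh)
        core = retweet.k_core(pruned, config.core_k)
        overlap = retweet.narrative_overlap(prof)
        retweet.export_edgelist(g, out / "retweet_edges.tsv")
        retweet.export_graphml(pruned, prof, out / "retweet_pruned.graphml")
        (out / "narrative_overlap.json").write_text(
            json.dumps(overlap, indent=2, sort_keys=True))
        summary["stages"]["retweet_network"] = {
            "n_nodes": g.number_of_nodes(), "n_ties": g.number_of_edges(),
            "n_pruned": len(removed), "core_k": config.core_k,
            "core_size": core.number_of_nodes(),
            "prominent": retweet.prominent_users(g, 5) if len(g) else [],
            "narrative_overlap": overlap,
            "elapsed_s": round(time.time() - t0, 3),
        }

        stage = "source_groups"
        t0 = time.time()
        consp = group_from_catalog(catalog, "conspiracy", config.group_size)
        quest = group_from_catalog(catalog, "questionable", config.group_size)
        shared = {d for tw in tweets for d in map(url_to_domain, tw.urls)
                  if d is not None}
        k = min(config.group_size,
                max(len(consp), len(quest)))
        rand = sample_random_sources(
            shared, consp.domains | quest.domains, k, config.seed)
        for grp in (consp, quest, rand):
            (out / f"group_{grp.name}.txt").write_text(
                "\n".join(sorted(grp.domains)) + "\n")
        summary["stages"]["source_groups"] = {
            "sizes": {g_.name: len(g_) for g_ in (consp, quest, rand)},
            "elapsed_s": round(time.time() - t0, 3),
        }

        stage = "cosharing"
        t0 = time.time()
        graphs = {g_.name: cosharing.build_coshare(tweets, g_)
                  for g_ in (consp, quest, rand)}
        metrics = {}
        for name in ("conspiracy", "questionable"):
            try:
                metrics[name] = cosharing.relative_metrics(
                    graphs[name], graphs["random"])
            except ValueError as exc:
                metrics[name] = {"error": str(exc)}
        metrics["random"] = {
            "avg_clustering": cosharing.avg_clustering(graphs["random"]),
            "avg_link_weight": cosharing.avg_link_weight(graphs["random"]),
            "relative_clustering": 1.0, "relative_link_weight": 1.0,
        }
        (out / "cosharing_metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True))
        summary["stages"]["cosharing"] = {
            "metrics": metrics, "elapsed_s": round(time.time() - t0, 3)}

        stage = "trends"
        t0 = time.time()
        counts = trends.daily_counts(tweets, [consp, quest, rand])
        counts.to_csv(out / "daily_counts.csv")
        fits = {}
        for name in ("conspiracy", "questionable"):
            try:
                fits[name] = trends.fit_trend(counts, name).to_dict()
            except ValueError as exc:
                fits[name] = {"error": str(exc)}
        (out / "trend_fits.json").write_text(
            json.dumps(fits, indent=2, sort_keys=True))
        weekly = trends.weekly_share_curve(counts, config.week_window)
        pd.concat([v.to_frame() for v in weekly.values()]).to_csv(
            out / "weekly_curves.csv", index=False)
        summary["stages"]["trends"] = {
            "fits": fits, "n_days": len(counts),
            "elapsed_s": round(time.time() - t0, 3)}

        stage = "temporal_topics"
        t0 = time.time()
        if config.run_shape_clustering:
            series = temporal.extract_bigrams(tweets, config.top_n_bigrams)
            if not series.empty:
                series.to_csv(out / "bigram_series.csv")
            clusters = []
            try:
                found = temporal.shape_cluster(
                    series, config.shape_k, config.shape_window_days,
                    config.burst_fraction, seed=config.seed)
                clusters = [
                    {"cluster_id": c.cluster_id, "peak_week": c.peak_week,
                     "members": sorted(c.members)}
                    for c in found
                ]
            except ValueError as exc:
                logger.warning("shape clustering skipped: %s", exc)
                clusters = [{"error": str(exc)}]
            (out / "shape_clusters.json").write_text(
                json.dumps(clusters, indent=2, sort_keys=True))
            summary["stages"]["temporal_topics"] = {
                "n_bigrams": int(len(series)),
                "n_clusters": len([c for c in clusters if "error" not in c]),
                "elapsed_s": round(time.time() - t0, 3),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # elapsed times vary run to run; the byte-stable summary excludes them
    stable = json.loads(json.dumps(summary))
    for st in stable["stages"].values():
        st.pop("elapsed_s", None)
    (out / "summary.json").write_text(
        json.dumps(stable, indent=2, sort_keys=True) + "\n")
    return summary
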