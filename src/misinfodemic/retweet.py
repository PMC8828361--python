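"""Retweet-network construction and echo-chamber structure.

The graph is directed retweeted → retweeter, i.e. along the direction of
information flow, so a widely retweeted account has high out-degree. Only
retweets made by misinformation-engaged users enter the graph (the standard
audience restriction for a misinformation retweet network); any retweet by
such a user counts, whether or not that particular retweet carried an
unreliable URL.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd

from .io import TweetRecord

__all__ = ["build_retweet_graph", "prominent_users", "prune_bots", "k_core",
           "narrative_overlap", "overlap_percent", "original_tweet_counts"]


def build_retweet_graph(
    tweets: list[TweetRecord], profiles: pd.DataFrame
) -> nx.DiGraph:
    """Weighted directed graph: edge retweeted_user → retweeting_user with
    weight = number of retweets between the pair; restricted to retweets
    whose retweeting user is misinformation-engaged; no self-loops."""
    engaged = set(profiles.loc[profiles.misinfo_engaged, "user_id"])
    g = nx.DiGraph()
    for tw in tweets:
        if not tw.is_retweet or tw.user_id not in engaged:
            continue
        src, dst = tw.retweeted_user_id, tw.user_id
        if src == dst:
            continue
        if g.has_edge(src, dst):
            g[src][dst]["weight"] += 1
        else:
            g.add_edge(src, dst, weight=1)
    return g


def prominent_users(graph: nx.DiGraph, n: int) -> list[tuple[str, int]]:
    """Top-n users by out-degree (distinct retweeters, unweighted); ties
    broken by user id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    degs = [(u, graph.out_degree(u)) for u in graph.nodes]
    degs.sort(key=lambda t: (-t[1], t[0]))
    return degs[:n]


def original_tweet_counts(tweets: list[TweetRecord]) -> dict[str, int]:
    """Per-user count of original (non-retweet) tweets."""
    counts: dict[str, int] = {}
    for tw in tweets:
        if not tw.is_retweet:
            counts[tw.user_id] = counts.get(tw.user_id, 0) + 1
    return counts


def prune_bots(
    graph: nx.DiGraph,
    tweet_counts: dict[str, int],
    rate_threshold: float,
) -> tuple[nx.DiGraph, list[str]]:
    """Remove bot-like nodes: tweet count >= rate_threshold AND never
    retweeted (zero out-degree under the information-flow orientation).
    Returns (pruned copy, removed node list)."""
    removed = sorted(
        u for u in graph.nodes
        if tweet_counts.get(u, 0) >= rate_threshold and graph.out_degree(u) == 0
    )
    pruned = graph.copy()
    pruned.remove_nodes_from(removed)
    return pruned, removed


def k_core(graph: nx.DiGraph | nx.Graph, k: int) -> nx.Graph:
    """Maximal induced subgraph where every node has >= k distinct
    neighbors, computed on the undirected simplification. May be empty."""
    if k < 1:
        raise ValueError("k must be >= 1")
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    und.add_edges_from((u, v) for u, v in graph.edges if u != v)
    return nx.k_core(und, k)


def overlap_percent(count: int, total: int) -> int:
    """Percentage of tagged users, rounded to the nearest integer (the form
    overlap shares are reported in)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count / total))


def narrative_overlap(profiles: pd.DataFrame) -> dict:
    """Exact Venn partition of users over the three narrative tags.

    Returns counts for the 7 nonempty tag subsets (keys like
    "HCQ|PREVENTION", components sorted), "total_tagged", and a parallel
    "percent" mapping rounded to the nearest integer.
    """
    names = sorted({n for s in profiles.narratives for n in s.split("|") if n})
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts["|".join(combo)] = 0
    total = 0
    for narr in profiles.narratives:
        tags = sorted(t for t in narr.split("|") if t)
        if not tags:
            continue
        total += 1
        counts["|".join(tags)] += 1
    return {
        "counts": counts,
        "total_tagged": total,
        "percent": {
            key: overlap_percent(c, total) if total else 0
            for key, c in counts.items()
        },
    }


def export_edgelist(graph: nx.DiGraph, path) -> None:
    """Weighted edge list TSV (src, dst, weight)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("src\tdst\tweight\n")
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w}\n")


def export_graphml(graph: nx.DiGraph, profiles: pd.DataFrame, path) -> None:
    """GraphML export carrying lean and narrative attributes for external
    layout tools."""
    g = graph.copy()
    attrs = profiles.set_index("user_id")
    for u in g.nodes:
        if u in attrs.index:
            g.nodes[u]["lean"] = str(attrs.at[u, "lean"])
            g.nodes[u]["narratives"] = str(attrs.at[u, "narratives"])
    nx.write_graphml(g, path)
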