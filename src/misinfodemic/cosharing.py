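"""Domain co-sharing (audience) networks and their density statistics.

For a group of domains, an undirected edge joins two domains when at least
one user shared content from both; the edge weight is the number of such
users. Density is summarized by the average local clustering coefficient
(binarized graph, degree<2 nodes contribute 0) and the average link weight
taken over *all* unordered node pairs (absent links count 0) — the
all-pairs denominator is what makes a sparse random-baseline group come out
near zero. Both statistics are also reported relative to a random-baseline
group, with the baseline normalized to 1.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

from .io import SourceGroup, TweetRecord, url_to_domain

__all__ = ["build_coshare", "avg_clustering", "avg_link_weight",
           "relative_metrics"]


def build_coshare(tweets: list[TweetRecord], group: SourceGroup) -> nx.Graph:
    """Co-sharing graph over the group's domains; every group domain is a
    node even if isolated."""
    if not len(group):
        raise ValueError("group is empty")
    shared_by: dict[str, set[str]] = {}
    for tw in tweets:
        for url in tw.urls:
            dom = url_to_domain(url)
            if dom in group.domains:
                shared_by.setdefault(tw.user_id, set()).add(dom)
    g = nx.Graph(name=group.name)
    g.add_nodes_from(group.domains)
    for doms in shared_by.values():
        for a, b in combinations(sorted(doms), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def avg_clustering(graph: nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes, unweighted;
    degree<2 nodes contribute 0; empty graph gives 0."""
    if graph.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(graph, count_zeros=True))


def avg_link_weight(graph: nx.Graph, existing_only: bool = False) -> float:
    """Sum of edge weights divided by n(n-1)/2 (all unordered pairs; absent
    edges count 0). ``existing_only=True`` divides by the edge count
    instead."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    total = sum(w for _, _, w in graph.edges(data="weight", default=1))
    if existing_only:
        m = graph.number_of_edges()
        return total / m if m else 0.0
    return total / (n * (n - 1) / 2)


def relative_metrics(target: nx.Graph, baseline: nx.Graph) -> dict:
    """Density of ``target`` relative to the random ``baseline`` group.

    Returns absolute and relative average clustering coefficient and
    average link weight; the baseline's own relative values are exactly 1.
    """
    base_cc = avg_clustering(baseline)
    base_lw = avg_link_weight(baseline)
    if base_cc == 0 or base_lw == 0:
        raise ValueError(
            "baseline density is zero — use a denser random sample or more "
            "data before computing ratios"
        )
    cc = avg_clustering(target)
    lw = avg_link_weight(target)
    return {
        "avg_clustering": cc,
        "avg_link_weight": lw,
        "baseline_avg_clustering": base_cc,
        "baseline_avg_link_weight": base_lw,
        "relative_clustering": cc / base_cc,
        "relative_link_weight": lw / base_lw,
    }
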