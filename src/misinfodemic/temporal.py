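"""Weekly bigram time series, shape-based temporal clustering, and
coherence-selected topic modelling.

Bigrams are consecutive token pairs after case-folding, punctuation/hash
stripping and stop-word removal. Each retained bigram gets a weekly series
of its count divided by the total number of bigram tokens used that week
(totals counted over *all* bigrams, not just the retained top-n).

``shape_cluster`` groups bigrams whose popularity curves have similar
temporal shape. It is a deliberately simple, fully reproducible procedure:
a burst filter keeps only bigrams whose best contiguous window of the
configured length holds at least a given fraction of their total mass
(dropping perennial phrases that dominate every week), survivors are
z-normalized, and k-means clusters the standardized curves (Euclidean
distance on z-scored rows is a monotone transform of one minus the Pearson
correlation, so this is correlation-shape clustering). Clusters are
reported in order of peak week.

``topic_model`` wraps latent Dirichlet allocation, fitting each candidate
topic count and selecting the one with the highest mean UMass coherence
(log document co-occurrence ratios over each topic's top terms).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from ._text import tokenize_content
from .io import TweetRecord
from .subset import _week_start

__all__ = ["TemporalCluster", "extract_bigrams", "shape_cluster",
           "burst_filter", "topic_model"]


@dataclass(frozen=True)
class TemporalCluster:
    cluster_id: int
    members: frozenset[str]
    shape: tuple[float, ...]   # mean z-normalized series
    peak_week: int             # argmax of shape (week index)


def tweet_bigrams(text: str) -> list[str]:
    toks = tokenize_content(text)
    return [f"{a} {b}" for a, b in zip(toks, toks[1:])]


def extract_bigrams(tweets: list[TweetRecord], top_n: int) -> pd.DataFrame:
    """Weekly normalized frequency table of the overall top-n bigrams.

    Returns a DataFrame indexed by bigram with one column per ISO week
    (Monday date); each entry is that bigram's count in the week divided by
    the week's total bigram-token count. Interior weeks with no tweets get
    zero columns. Deterministic; frequency ties in top-n selection break
    lexicographically.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    weekly: dict[date, Counter] = {}
    overall: Counter = Counter()
    for tw in tweets:
        wk = _week_start(tw.timestamp.date())
        bgs = tweet_bigrams(tw.text)
        if not bgs:
            continue
        cnt = weekly.setdefault(wk, Counter())
        for bg in bgs:
            cnt[bg] += 1
            overall[bg] += 1
    if not overall:
        return pd.DataFrame()
    lo, hi = min(weekly), max(weekly)
    weeks = pd.date_range(lo, hi, freq="7D").date
    totals = {wk: sum(weekly[wk].values()) for wk in weekly}
    top = sorted(overall.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    rows = {}
    for bg, _ in top:
        rows[bg] = [
            (weekly.get(wk, Counter()).get(bg, 0) / totals[wk])
            if totals.get(wk) else 0.0
            for wk in weeks
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(weeks))
    df.index.name = "bigram"
    return df


def _best_window_fraction(series: np.ndarray, w: int) -> float:
    """Largest fraction of total mass held by any contiguous window of
    length w (in series steps)."""
    total = series.sum()
    if total <= 0:
        return 0.0
    w = min(w, len(series))
    c = np.concatenate([[0.0], np.cumsum(series)])
    windows = c[w:] - c[:-w]
    return float(windows.max() / total)


def burst_filter(series: pd.DataFrame, window_days: int,
                 burst_fraction: float) -> pd.DataFrame:
    """Keep bigrams whose best window of ``window_days`` holds at least
    ``burst_fraction`` of their total normalized mass. Scale-invariant:
    multiplying a series by a positive constant cannot change its decision.
    """
    w_weeks = max(1, round(window_days / 7))
    keep = [
        bg for bg in series.index
        if _best_window_fraction(series.loc[bg].to_numpy(float), w_weeks)
        >= burst_fraction
    ]
    return series.loc[keep]


def shape_cluster(
    series: pd.DataFrame,
    k: int,
    window_days: int = 21,
    burst_fraction: float = 0.5,
    seed: int = 0,
) -> list[TemporalCluster]:
    """Burst-filter, z-normalize and k-means the weekly bigram curves;
    clusters come back ordered by their peak week."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if window_days < 7:
        raise ValueError("window_days must be >= 7")
    if series.empty:
        raise ValueError("series table is empty")
    surv = burst_filter(series, window_days, burst_fraction)
    if len(surv) < k:
        raise ValueError(
            f"k={k} exceeds the {len(surv)} bigrams surviving the burst "
            f"filter (of {len(series)} input)"
        )
    x = surv.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=200)
    labels = km.fit_predict(z)
    clusters = []
    for lab in range(k):
        mask = labels == lab
        members = frozenset(surv.index[mask])
        shape = z[mask].mean(axis=0)
        clusters.append((int(np.argmax(shape)), members, shape))
    clusters.sort(key=lambda t: (t[0], sorted(t[1])[0]))
    return [
        TemporalCluster(i, members, tuple(float(v) for v in shape), peak)
        for i, (peak, members, shape) in enumerate(clusters)
    ]


def _umass_coherence(topic_terms: list[int], doc_term: np.ndarray) -> float:
    """UMass coherence of one topic: sum over ordered top-term pairs of
    log((D(wi,wj)+1)/D(wj)) with document frequencies D from the corpus."""
    present = doc_term > 0
    score = 0.0
    for i in range(1, len(topic_terms)):
        for j in range(i):
            wi, wj = topic_terms[i], topic_terms[j]
            d_j = present[:, wj].sum()
            if d_j == 0:
                continue
            d_ij = (present[:, wi] & present[:, wj]).sum()
            score += float(np.log((d_ij + 1) / d_j))
    return score


def topic_model(
    tweets: list[TweetRecord] | list[str],
    n_candidates: list[int],
    seed: int = 0,
    n_top_terms: int = 10,
) -> tuple[int, list[list[str]], dict[int, float]]:
    """Fit LDA for each candidate topic count; pick the count with the
    highest mean per-topic UMass coherence.

    Returns (chosen_n, topics as top-term lists for the chosen model,
    mean coherence per candidate). Deterministic at fixed seed.
    """
    texts = [tw if isinstance(tw, str) else tw.text for tw in tweets]
    if len(texts) < 50:
        raise ValueError(f"need >= 50 documents, got {len(texts)}")
    vec = CountVectorizer(analyzer=tokenize_content)
    dt = vec.fit_transform(texts)
    if dt.shape[1] == 0:
        raise ValueError("empty vocabulary after preprocessing")
    dt_arr = np.asarray(dt.todense())
    vocab = vec.get_feature_names_out()
    coherences: dict[int, float] = {}
    models: dict[int, list[list[int]]] = {}
    for n in n_candidates:
        lda = LatentDirichletAllocation(
            n_components=n, random_state=seed, max_iter=20)
        lda.fit(dt)
        tops = [
            list(np.argsort(comp)[::-1][:n_top_terms])
            for comp in lda.components_
        ]
        models[n] = tops
        coherences[n] = float(
            np.mean([_umass_coherence(t, dt_arr) for t in tops]))
    chosen = max(n_candidates, key=lambda n: (coherences[n], -n))
    topics = [[str(vocab[i]) for i in terms] for terms in models[chosen]]
    return chosen, topics, coherences
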