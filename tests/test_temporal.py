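from collections import Counter
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from misinfodemic._text import tokenize_content
from misinfodemic.io import TweetRecord
from misinfodemic.temporal import (
    burst_filter,
    extract_bigrams,
    shape_cluster,
    topic_model,
    tweet_bigrams,
)

T0 = datetime(2020, 3, 2, tzinfo=timezone.utc)  # a Monday


def tweet(i, text, day=0):
    return TweetRecord(tweet_id=f"t{i}", user_id=f"u{i}",
                       timestamp=T0 + timedelta(days=day), text=text)


class TestTokenizationAndBigrams:
    def test_worked_example(self):
        text = "Thousands of new #covid cases reported in Los Angeles County!!"
        assert tokenize_content(text) == [
            "thousands", "new", "covid", "cases", "reported", "los",
            "angeles", "county",
        ]
        bgs = tweet_bigrams(text)
        assert bgs[:4] == ["thousands new", "new covid", "covid cases",
                           "cases reported"]

    def test_stop_word_only_text_has_no_bigrams(self):
        assert tweet_bigrams("a a a") == []

    def test_hash_sign_stripped(self):
        assert "covid cases" in tweet_bigrams("#covid #cases")


class TestExtractBigrams:
    def test_top_n_keeps_dominant_bigram(self):
        tweets = [tweet(i, "covid cases") for i in range(5)]
        tweets += [tweet(9, "vaccine news update")]
        series = extract_bigrams(tweets, top_n=1)
        assert list(series.index) == ["covid cases"]

    def test_weekly_normalization_matches_brute_force(self):
        tweets = [
            tweet(0, "covid cases rising fast", day=0),   # week 0
            tweet(1, "covid cases again", day=1),         # week 0
            tweet(2, "vaccine news", day=7),              # week 1
            tweet(3, "covid cases", day=8),               # week 1
        ]
        series = extract_bigrams(tweets, top_n=100)
        # brute force: per-week bigram totals over all bigrams
        week_of = lambda d: (T0 + timedelta(days=d)).date() - timedelta(
            days=(T0 + timedelta(days=d)).weekday())
        raw = {}
        for tw, day in zip(tweets, (0, 1, 7, 8)):
            wk = week_of(day)
            for bg in tweet_bigrams(tw.text):
                raw.setdefault(wk, Counter())[bg] += 1
        for wk, counts in raw.items():
            total = sum(counts.values())
            for bg, c in counts.items():
                assert series.at[bg, wk] == pytest.approx(c / total)

    def test_row_entries_in_unit_interval(self, small_stream):
        series = extract_bigrams(small_stream[:2000], top_n=200)
        vals = series.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_empty_input(self):
        assert extract_bigrams([], 10).empty


class TestBurstFilter:
    WEEKS = [f"w{i}" for i in range(52)]

    def test_flat_series_filtered_out(self):
        flat = pd.DataFrame([[0.01] * 52], index=["covid cases"],
                            columns=self.WEEKS)
        # best 3-week window holds 3/52 of the mass, well below 0.5
        assert burst_filter(flat, 21, 0.5).empty

    def test_bursty_series_kept(self):
        row = [0.0] * 52
        row[20:23] = [0.3, 0.5, 0.3]
        bursty = pd.DataFrame([row], index=["lab leak"], columns=self.WEEKS)
        assert list(burst_filter(bursty, 21, 0.5).index) == ["lab leak"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.random((10, 52)), columns=self.WEEKS,
                            index=[f"b{i}" for i in range(10)])
        for factor in (0.01, 1.0, 250.0):
            assert burst_filter(base * factor, 21, 0.5).index.equals(
                burst_filter(base, 21, 0.5).index
            )


class TestShapeCluster:
    @staticmethod
    def _bump_series(names_peaks, n_weeks=40):
        rows = {}
        for name, peak in names_peaks:
            x = np.exp(-0.5 * ((np.arange(n_weeks) - peak) / 1.5) ** 2)
            rows[name] = x / x.sum()
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_identical_series_single_cluster(self):
        series = self._bump_series([("a b", 10), ("c d", 10)])
        clusters = shape_cluster(series, k=1, seed=0)
        assert clusters[0].members == {"a b", "c d"}

    def test_clusters_ordered_by_peak_week(self):
        series = self._bump_series(
            [("a b", 30), ("c d", 5), ("e f", 18), ("g h", 31),
             ("i j", 4), ("k l", 17)])
        clusters = shape_cluster(series, k=3, seed=0)
        peaks = [c.peak_week for c in clusters]
        assert peaks == sorted(peaks)
        assert clusters[0].members == {"c d", "i j"}
        assert clusters[2].members == {"a b", "g h"}

    def test_partition_and_label_invariance(self):
        series = self._bump_series(
            [(f"x{i} y{i}", p) for i, p in enumerate([3, 4, 20, 21, 35, 36])])
        a = shape_cluster(series, k=3, seed=9)
        b = shape_cluster(series.iloc[::-1], k=3, seed=9)
        parts_a = {frozenset(c.members) for c in a}
        parts_b = {frozenset(c.members) for c in b}
        assert parts_a == parts_b
        assert set().union(*parts_a) == set(series.index)

    def test_k_exceeding_survivors_raises(self):
        series = self._bump_series([("a b", 10)])
        with pytest.raises(ValueError, match="surviv"):
            shape_cluster(series, k=5, seed=0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            shape_cluster(pd.DataFrame(), k=2)


class TestTopicModel:
    @staticmethod
    def _separable_corpus(n_docs=120, seed=0):
        rng = np.random.default_rng(seed)
        vocab_a = ["vaccine", "trial", "dose", "pfizer", "moderna",
                   "efficacy"]
        vocab_b = ["lockdown", "protest", "police", "street", "curfew",
                   "crowd"]
        return [
            " ".join(rng.choice(vocab_a if i % 2 else vocab_b, size=8))
            for i in range(n_docs)
        ]

    def test_coherence_selects_true_topic_count(self):
        docs = self._separable_corpus()
        chosen, topics, coherences = topic_model(docs, [2, 5], seed=0)
        assert chosen == 2
        assert len(topics) == 2
        # the two topics separate the two vocabularies
        tops = [set(t[:4]) for t in topics]
        assert any(t <= {"vaccine", "trial", "dose", "pfizer", "moderna",
                         "efficacy"} for t in tops)

    def test_deterministic_at_fixed_seed(self):
        docs = self._separable_corpus()
        a = topic_model(docs, [2, 3], seed=5)
        b = topic_model(docs, [2, 3], seed=5)
        assert a == b

    def test_single_candidate_returned_directly(self):
        chosen, topics, _ = topic_model(self._separable_corpus(), [1], seed=0)
        assert chosen == 1 and len(topics) == 1

    def test_too_few_documents(self):
        with pytest.raises(ValueError, match="50"):
            topic_model(["covid news"] * 10, [2])

    def test_empty_vocabulary(self):
        with pytest.raises(ValueError, match="vocabulary"):
            topic_model(["the and of"] * 60, [2])
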