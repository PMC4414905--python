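"""Distribution tables, item shares, co-occurrence, recommendation share."""

import numpy as np
import pandas as pd
import pytest

from hospmine import analytics
from hospmine.pipeline import run_stages
from hospmine.synthetic import (
    GeneratorConfig,
    generate_cooccurrence_corpus,
    generate_corpus,
)


def _instance_frame(rows):
    """Build a minimal instance table from (region, year, factor, keyword, polarity)."""
    recs = []
    for i, (region, year, factor, keyword, polarity) in enumerate(rows):
        recs.append(
            {
                "message_id": f"m{i}",
                "thread_id": f"t{i}",
                "region": region,
                "year": year,
                "month": 1,
                "factor": factor,
                "subcategory": "f15",
                "keyword": keyword,
                "sentence_index": 0,
                "polarity": polarity,
                "binary": {"positive": "positive", "negative": "negative",
                           "bilateral": "negative", "neutral": "excluded"}[polarity],
                "canonical_id": "H1",
            }
        )
    return pd.DataFrame(recs)


class TestFactorDistribution:
    def test_even_split(self):
        rows = [("Seoul", 2009, "process", "k", "positive")] * 50 + [
            ("Seoul", 2009, "service", "k", "positive")
        ] * 50
        dist = analytics.factor_distribution(_instance_frame(rows), by=("region",))
        assert sorted(dist["share_pct"]) == [50.0, 50.0]

    def test_single_factor_is_100(self):
        dist = analytics.factor_distribution(
            _instance_frame([("Seoul", 2009, "process", "k", "positive")] * 7)
        )
        assert list(dist["share_pct"]) == [100.0]

    def test_groups_sum_to_100(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=13, n_threads_per_region=12, factor_message_prob=0.8)
        threads, messages, _ = generate_corpus(cfg, *bundled_lexicons)
        res = run_stages(threads, messages, *bundled_lexicons)
        for by in [("region",), ("region", "year"), ("year", "month")]:
            dist = analytics.factor_distribution(res.instance_table, by=by)
            sums = dist.groupby(list(by))["share_pct"].sum()
            assert np.allclose(sums, 100.0, atol=0.02)

    def test_filter_then_distribute_commutes(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=14, n_threads_per_region=12, factor_message_prob=0.8)
        threads, messages, _ = generate_corpus(cfg, *bundled_lexicons)
        res = run_stages(threads, messages, *bundled_lexicons)
        table = res.instance_table
        via_filter_arg = analytics.factor_distribution(
            table, by=("region",), polarity_filter="negative"
        )
        pre_filtered = analytics.factor_distribution(
            table[table["binary"] == "negative"], by=("region",)
        )
        pd.testing.assert_frame_equal(
            via_filter_arg.reset_index(drop=True), pre_filtered.reset_index(drop=True)
        )

    def test_monthly_counts_aggregate_to_yearly(self, bundled_lexicons):
        cfg = GeneratorConfig(seed=15, n_threads_per_region=15, factor_message_prob=0.9)
        threads, messages, _ = generate_corpus(cfg, *bundled_lexicons)
        res = run_stages(threads, messages, *bundled_lexicons)
        monthly = analytics.factor_distribution(res.instance_table, by=("year", "month"))
        yearly = analytics.factor_distribution(res.instance_table, by=("year",))
        # count-weighted roll-up of monthly counts equals the yearly table
        rolled = (
            monthly.groupby(["year", "factor"], observed=True)["count"].sum().reset_index()
        )
        merged = rolled.merge(yearly, on=["year", "factor"], suffixes=("_m", "_y"))
        assert (merged["count_m"] == merged["count_y"]).all()

    def test_recovers_planted_regional_mixture(self, bundled_lexicons):
        hospitals, factors, sentiment = bundled_lexicons
        weights = {"long term": 50, "kind nurse": 30, "reservation": 20}
        cfg = GeneratorConfig(
            seed=16,
            n_threads_per_region=40,
            regions=("Seoul",),
            factor_message_prob=1.0,
            max_factor_mentions=3,
            factor_keyword_weights=tuple(weights.items()),
            p_positive=1.0, p_negative=0.0, p_bilateral=0.0,
        )
        threads, messages, gold = generate_corpus(cfg, hospitals, factors, sentiment)
        res = run_stages(threads, messages, hospitals, factors, sentiment)
        dist = analytics.factor_distribution(res.instance_table, by=("region",))
        shares = dist.set_index("factor")["share_pct"]
        n = dist["count"].sum()
        assert n > 300
        for factor, expected in [("process", 50.0), ("service", 30.0), ("environment", 20.0)]:
            se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
            assert abs(shares[factor] - expected) < 3 * se + 1e-9


class TestNegativeShare:
    def test_counts_bilateral_as_negative(self):
        rows = (
            [("Seoul", 2009, "process", "k", "negative")] * 2
            + [("Seoul", 2009, "process", "k", "bilateral")] * 1
            + [("Seoul", 2009, "process", "k", "positive")] * 7
        )
        out = analytics.negative_share(_instance_frame(rows), by=("year",))
        assert out.loc[0, "negative_pct"] == 30.0  # (2+1)/10

    def test_neutral_excluded_by_default(self):
        rows = [("Seoul", 2009, "process", "k", "negative")] * 1 + [
            ("Seoul", 2009, "process", "k", "neutral")
        ] * 9
        out = analytics.negative_share(_instance_frame(rows), by=("year",))
        assert out.loc[0, "negative_pct"] == 100.0
        out_all = analytics.negative_share(
            _instance_frame(rows), by=("year",), include_neutral=True
        )
        assert out_all.loc[0, "negative_pct"] == 10.0


class TestItemShare:
    def test_planted_shares_reproduced_exactly(self):
        counts = {"long term": 73, "right now": 11, "hospitalized": 10, "basic": 5, "dose standby": 1}
        rows = []
        for kw, n in counts.items():
            rows += [("Seoul", 2009, "process", kw, "negative")] * n
        table = analytics.item_share(
            _instance_frame(rows), "process", polarity_filter="negative", year=2009
        )
        assert list(table["keyword"]) == ["long term", "right now", "hospitalized", "basic", "dose standby"]
        assert list(table["share_pct"]) == [73.0, 11.0, 10.0, 5.0, 1.0]

    def test_single_item_is_100(self):
        table = analytics.item_share(
            _instance_frame([("Seoul", 2009, "process", "k", "negative")]), "process"
        )
        assert list(table["share_pct"]) == [100.0]

    def test_order_invariance(self):
        rows = [("Seoul", 2009, "process", k, "negative") for k in "abcab"]
        shuffled = list(reversed(rows))
        t1 = analytics.item_share(_instance_frame(rows), "process")
        t2 = analytics.item_share(_instance_frame(shuffled), "process")
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_factor(self):
        with pytest.raises(ValueError):
            analytics.item_share(_instance_frame([]), "velocity")


class TestCooccurrence:
    def _run(self, bundled_lexicons, probs, n_threads, seed=21):
        hospitals, factors, sentiment = bundled_lexicons
        threads, messages, _ = generate_cooccurrence_corpus(
            term="emergency",
            hospital_probs=probs,
            filler_id="DAE6",
            n_threads=n_threads,
            seed=seed,
            region="Daegu",
            hospitals=hospitals,
            sentiment=sentiment,
        )
        res = run_stages(threads, messages, hospitals, factors, sentiment)
        return analytics.cooccurrence(
            threads, messages, res.hospital_mentions, res.labels, "emergency"
        )

    def test_absent_term_gives_empty_table(self, bundled_lexicons):
        table = self._run(bundled_lexicons, {"DAE1": 1.0}, n_threads=5)
        hospitals, factors, sentiment = bundled_lexicons
        # same corpus, query a term that never occurs
        threads, messages, _ = generate_cooccurrence_corpus(
            "emergency", {"DAE1": 1.0}, "DAE6", 5, 21, "Daegu", hospitals, sentiment
        )
        res = run_stages(threads, messages, hospitals, factors, sentiment)
        empty = analytics.cooccurrence(
            threads, messages, res.hospital_mentions, res.labels, "unseenword"
        )
        assert empty.empty and empty.attrs["denominator"] == 0

    def test_single_thread_is_100(self, bundled_lexicons):
        table = self._run(bundled_lexicons, {"DAE1": 1.0}, n_threads=1)
        assert list(table["canonical_id"]) == ["DAE1"]
        assert list(table["cooccurrence_pct"]) == [100.0]
        assert table.attrs["denominator"] == 1

    def test_planted_shares_recovered(self, bundled_lexicons):
        probs = {"DAE1": 0.22, "DAE2": 0.16, "DAE3": 0.07, "DAE4": 0.31, "DAE5": 0.08}
        n = 600
        table = self._run(bundled_lexicons, probs, n_threads=n).set_index("canonical_id")
        assert table.attrs["denominator"] == n
        for cid, p in probs.items():
            se = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(table.loc[cid, "cooccurrence_pct"] - 100 * p) < 3 * se


class TestRecommendationShare:
    def test_published_counts(self):
        assert analytics.recommendation_share(47046, 131191) == 35.86

    def test_edges(self):
        assert analytics.recommendation_share(0, 10) == 0.0
        assert analytics.recommendation_share(10, 10) == 100.0
        assert analytics.recommendation_share(0, 0) == 0.0

    def test_from_instance_table(self):
        rows = [("Seoul", 2009, "process", "k", "positive")] * 3 + [
            ("Seoul", 2009, "process", "k", "neutral")
        ] * 1
        assert analytics.recommendation_share(_instance_frame(rows)) == 75.0
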