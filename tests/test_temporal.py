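from collections import Counter

import numpy as np
import pytest

from medtweet.temporal import (
    DEFAULT_PERIODS,
    TimeBinSpec,
    aggregate_counts,
    kruskal_wallis,
    monthly_seasonality_test,
    period_proportions,
)

from conftest import make_tweet


def kruskal_wallis_bruteforce(groups):
    """Independent midrank implementation of the tie-corrected H statistic."""
    pooled = sorted(x for g in groups for x in g)
    n_total = len(pooled)
    midrank = {}
    i = 0
    while i < n_total:
        j = i
        while j < n_total and pooled[j] == pooled[i]:
            j += 1
        midrank[pooled[i]] = (i + 1 + j) / 2  # average of ranks i+1..j
        i = j
    h = 12 / (n_total * (n_total + 1)) * sum(
        sum(midrank[x] for x in g) ** 2 / len(g) for g in groups
    ) - 3 * (n_total + 1)
    ties = Counter(pooled)
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n_total**3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_hand_worked_three_group_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.H == pytest.approx(7.2)
        assert res.df == 2
        assert res.group_sizes == (3, 3, 3)

    def test_identical_rank_sums_give_zero(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.H == pytest.approx(0.0)

    def test_all_equal_observations_degenerate(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.H == 0.0 and res.p_value == 1.0

    def test_agrees_with_bruteforce_midranks_on_random_instances(self):
        """100 random small instances (with ties) match to 1e-10."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(2, 10))).tolist()
                for _ in range(k)
            ]
            if len({x for g in groups for x in g}) == 1:
                continue
            res = kruskal_wallis(groups)
            assert res.H == pytest.approx(
                kruskal_wallis_bruteforce(groups), abs=1e-10
            )

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(size=6).tolist() for _ in range(3)]
        transformed = [[np.exp(3 * x) for x in g] for g in groups]
        assert kruskal_wallis(groups).H == pytest.approx(
            kruskal_wallis(transformed).H, abs=1e-10
        )

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestAggregate:
    def test_empty_corpus_gives_all_zero_grid(self):
        grid = aggregate_counts([])
        assert grid.shape == (11, 8)
        assert (grid == 0).all().all()

    def test_single_tweet_lands_in_its_year_cell(self):
        tweet = make_tweet("a", when="2014-07-01", hashtags={"dairy"}, retweets=5)
        tweets = aggregate_counts([tweet], measure="tweets")
        retweets = aggregate_counts([tweet], measure="retweets")
        assert tweets.loc["2014", "dairy"] == 1
        assert retweets.loc["2014", "dairy"] == 5
        assert tweets.to_numpy().sum() == 1

    def test_grid_conserves_corpus_totals(self, default_corpus):
        assert aggregate_counts(default_corpus, measure="tweets").to_numpy().sum() == 1608
        assert (
            aggregate_counts(default_corpus, measure="retweets").to_numpy().sum()
            == 48_946
        )
        assert (
            aggregate_counts(default_corpus, measure="likes").to_numpy().sum()
            == 123_363
        )

    def test_date_outside_coverage_is_error(self):
        tweet = make_tweet("a", when="2021-01-01")
        with pytest.raises(ValueError, match="coverage"):
            aggregate_counts([tweet], spec=TimeBinSpec("year", 2009, 2019))

    def test_default_periods_cover_the_window(self):
        assert DEFAULT_PERIODS[0] == (2009, 2011)
        assert DEFAULT_PERIODS[-1] == (2018, 2019)
        spec = TimeBinSpec("custom_periods")
        grid = aggregate_counts(
            [make_tweet("a", when="2013-05-05", hashtags={"nuts"})], spec=spec
        )
        assert grid.loc["2012-2013", "nuts"] == 1

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError):
            TimeBinSpec("custom_periods", periods=((2009, 2012), (2012, 2015)))


class TestProportions:
    def test_single_nonzero_cell_is_100(self):
        grid = aggregate_counts([make_tweet("a", when="2014-01-01")])
        pct = period_proportions(grid)
        assert pct.loc["2014", "dairy"] == pytest.approx(100.0)
        assert pct.to_numpy().sum() == pytest.approx(100.0)

    def test_three_cell_arithmetic(self):
        corpus = (
            [make_tweet(f"a{i}", when="2009-01-01", hashtags={"dairy"}) for i in range(1)]
            + [make_tweet(f"b{i}", when="2010-01-01", hashtags={"dairy"}) for i in range(3)]
            + [make_tweet(f"c{i}", when="2011-01-01", hashtags={"dairy"}) for i in range(6)]
        )
        pct = period_proportions(aggregate_counts(corpus))
        assert pct.loc["2009", "dairy"] == pytest.approx(10.0)
        assert pct.loc["2010", "dairy"] == pytest.approx(30.0)
        assert pct.loc["2011", "dairy"] == pytest.approx(60.0)

    def test_cells_sum_to_100_on_default_corpus(self, default_corpus):
        for unit in ("year", "month_of_year", "custom_periods"):
            pct = period_proportions(
                aggregate_counts(default_corpus, spec=TimeBinSpec(unit))
            )
            assert pct.to_numpy().sum() == pytest.approx(100.0)

    def test_zero_grand_total_rejected(self):
        with pytest.raises(ValueError):
            period_proportions(aggregate_counts([]))


class TestMonthlySeasonality:
    def test_identical_months_give_p_one(self):
        corpus = [
            make_tweet(f"t{y}{m}", when=f"{y}-{m:02d}-15")
            for y in (2015, 2016)
            for m in range(1, 13)
        ]
        res = monthly_seasonality_test(corpus, "tweets")
        assert res.p_value == 1.0 and res.H == 0.0
        assert res.group_sizes == (2,) * 12

    def test_uniform_random_months_do_not_reject(self, default_corpus):
        """Under uniform month assignment the null holds; p stays large."""
        for measure in ("tweets", "retweets"):
            res = monthly_seasonality_test(default_corpus, measure)
            assert res.df == 11
            assert res.p_value > 0.05

    def test_extreme_concentration_rejects(self):
        # everything in January over 11 years: January ranks far above the rest
        corpus = [
            make_tweet(f"t{y}x{i}", when=f"{y}-01-10")
            for y in range(2009, 2020)
            for i in range(3)
        ]
        res = monthly_seasonality_test(corpus, "tweets")
        assert res.p_value < 0.05

    def test_requires_two_calendar_years(self):
        corpus = [make_tweet("a", when="2015-01-01"), make_tweet("b", when="2015-06-01")]
        with pytest.raises(ValueError, match="two calendar years"):
            monthly_seasonality_test(corpus)

    def test_per_category_variant_runs(self, default_corpus):
        res = monthly_seasonality_test(default_corpus, "tweets", per_category=True)
        assert res.df == 11
        assert all(size == 11 * 8 for size in res.group_sizes)
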