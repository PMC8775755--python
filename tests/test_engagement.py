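import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from medtweet.engagement import (
    engagement_odds_ratio,
    or_panel,
    round_half_up,
    summarize_categories,
)
from medtweet.synthetic_data import DEFAULT_TARGETS

from conftest import make_tweet

# Published raw per-category counts (tweets, likes, retweets) and the
# derived one-decimal cells recomputed from them by hand arithmetic.
# Two printed retweet/tweet cells in the source table are internally
# inconsistent with its own raw counts (red wine prints 33.8, processed
# meat 42.3); the recomputed values below are the arithmetically correct
# ones (33.7 and 42.4).
EXPECTED_DERIVED = {
    "red_meat": (7.9, 92.2, 31.1),
    "red_wine": (9.6, 75.4, 33.7),
    "soft_drinks": (3.7, 46.4, 33.8),
    "dairy": (45.0, 62.1, 27.1),
    "nuts": (19.7, 86.2, 27.7),
    "olive_oil": (1.9, 55.5, 38.9),
    "processed_meat": (2.4, 87.8, 42.4),
    "mediterranean_diet": (9.8, 126.9, 41.7),
}


def test_round_half_up_is_away_from_zero():
    assert round_half_up(2.735, 2) == 2.74
    assert round_half_up(-2.735, 2) == -2.74
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(46.433, 1) == 46.4


class TestSummarize:
    def test_published_margins_give_published_derived_cells(self, default_corpus):
        """Every percentage and per-tweet ratio recomputes from the raw counts."""
        rows, totals = summarize_categories(default_corpus)
        for row in rows:
            target = DEFAULT_TARGETS[row.category]
            assert (row.n_tweets, row.n_likes, row.n_retweets) == (
                target.n_tweets, target.n_likes, target.n_retweets,
            )
            _, _, pct, _, lpt, _, rpt = row.rounded()
            assert (pct, lpt, rpt) == EXPECTED_DERIVED[row.category]
        assert (totals.n_tweets, totals.n_likes, totals.n_retweets) == (
            1608, 123_363, 48_946,
        )

    def test_unrounded_percentages_sum_to_100(self, default_corpus):
        rows, _ = summarize_categories(default_corpus)
        assert math.isclose(sum(r.pct_tweets for r in rows), 100.0, abs_tol=1e-9)

    def test_two_tweet_toy_corpus(self):
        corpus = [
            make_tweet("a", hashtags={"dairy"}, likes=3, retweets=1),
            make_tweet("b", hashtags={"nuts"}, likes=1, retweets=0),
        ]
        rows, totals = summarize_categories(corpus)
        dairy = next(r for r in rows if r.category == "dairy")
        assert dairy.rounded()[1:] == (1, 50.0, 3, 3.0, 1, 1.0)
        assert totals.n_tweets == 2 and totals.n_likes == 4

    def test_empty_corpus_and_zero_categories(self):
        rows, totals = summarize_categories([])
        assert len(rows) == 8
        for row in rows:
            assert row.n_tweets == 0
            assert row.likes_per_tweet is None and row.retweets_per_tweet is None
        assert totals.n_tweets == 0

    def test_multi_category_tweet_counts_in_each_row_once_in_totals(self):
        corpus = [make_tweet("a", hashtags={"nuts", "redwine"}, likes=4)]
        rows, totals = summarize_categories(corpus)
        by_name = {r.category: r for r in rows}
        assert by_name["nuts"].n_tweets == 1 and by_name["red_wine"].n_tweets == 1
        assert totals.n_tweets == 1 and totals.n_likes == 4


class TestOddsRatio:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # events_a, trials_a, events_b, trials_b -> OR (lo, hi)
            ((19_925, 157, 2_786, 60), (2.73, 2.02, 3.69)),
            ((19_925, 157, 44_877, 723), (2.04, 1.72, 2.43)),
            ((6_546, 157, 19_590, 723), (1.54, 1.29, 1.83)),
            ((10, 5, 4, 2), (1.0, 0.13, 7.45)),
        ],
    )
    def test_published_and_hand_worked_examples(self, counts, expected):
        assert engagement_odds_ratio(*counts).rounded() == expected

    @given(x=st.integers(1, 10_000), n=st.integers(1, 10_000))
    def test_identity_case(self, x, n):
        assert engagement_odds_ratio(x, n, x, n).odds_ratio == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [(0, 1, 1, 1), (1, 0, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)])
    def test_zero_count_is_undefined(self, counts):
        with pytest.raises(ValueError, match="undefined"):
            engagement_odds_ratio(*counts)

    def test_reciprocity_and_log_symmetry_on_random_quadruples(self):
        """OR(a,b) * OR(b,a) == 1 with reciprocal-reflected CIs; the CI is
        symmetric about ln(OR) on the log scale (1000 random quadruples)."""
        rng = np.random.default_rng(20220111)
        quads = rng.integers(1, 100_000, size=(1000, 4))
        for ea, ta, eb, tb in quads:
            fwd = engagement_odds_ratio(int(ea), int(ta), int(eb), int(tb))
            rev = engagement_odds_ratio(int(eb), int(tb), int(ea), int(ta))
            assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0, abs=1e-12)
            assert fwd.ci_low * rev.ci_high == pytest.approx(1.0, rel=1e-12)
            assert fwd.ci_high * rev.ci_low == pytest.approx(1.0, rel=1e-12)
            log_mid = (math.log(fwd.ci_low) + math.log(fwd.ci_high)) / 2
            assert log_mid == pytest.approx(math.log(fwd.odds_ratio), abs=1e-12)


class TestOrPanel:
    def test_default_corpus_panel_vs_soft_drinks(self, default_corpus):
        rows, _ = summarize_categories(default_corpus)
        panel = or_panel(rows, "soft_drinks", "likes")
        assert [r.category for r in panel] == [
            "red_meat", "red_wine", "dairy", "nuts",
            "olive_oil", "processed_meat", "mediterranean_diet",
        ]
        meddiet = panel[-1]
        assert meddiet.rounded() == (2.73, 2.02, 3.69)

    def test_meddiet_vs_dairy_contrasts(self, default_corpus):
        rows, _ = summarize_categories(default_corpus)
        likes = next(
            r for r in or_panel(rows, "dairy", "likes")
            if r.category == "mediterranean_diet"
        )
        retweets = next(
            r for r in or_panel(rows, "dairy", "retweets")
            if r.category == "mediterranean_diet"
        )
        assert likes.rounded() == (2.04, 1.72, 2.43)
        assert retweets.rounded() == (1.54, 1.29, 1.83)

    def test_single_category_corpus_gives_empty_panel(self):
        rows, _ = summarize_categories([make_tweet("a", hashtags={"dairy"}, likes=2)])
        assert or_panel(rows, "dairy", "likes") == []

    def test_zero_count_category_skipped_with_notice(self, caplog):
        corpus = [
            make_tweet("a", hashtags={"dairy"}, likes=5, retweets=1),
            make_tweet("b", hashtags={"nuts"}, likes=0, retweets=0),
        ]
        rows, _ = summarize_categories(corpus)
        with caplog.at_level("INFO"):
            panel = or_panel(rows, "dairy", "likes")
        assert panel == []
        assert any("nuts" in r.message for r in caplog.records)

    def test_missing_reference_is_error(self, default_corpus):
        rows, _ = summarize_categories(default_corpus)
        with pytest.raises(ValueError, match="reference"):
            or_panel(rows, "fish", "likes")
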