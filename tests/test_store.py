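"""Tweet archive parsing, windowing, labeling and cascade construction."""

import datetime as dt
import json

import numpy as np
import pytest

from mythcast.store import (
    Cascade,
    TweetRecord,
    UserProfile,
    build_cascade,
    category_tweet_share,
    label_tweets,
    read_tweets,
    window_filter,
    write_tweets,
)

UTC = dt.timezone.utc


def _record(tweet_id, user_id, day, text, **kw):
    return TweetRecord(
        tweet_id=tweet_id,
        user=UserProfile(user_id=user_id),
        created_at=dt.datetime(2020, 1, 1, 12, tzinfo=UTC) + dt.timedelta(days=day),
        text=text,
        **kw,
    )


class TestReadWrite:
    def test_three_line_fixture(self, tmp_path):
        p = tmp_path / "t.jsonl"
        lines = [
            {
                "id": i,
                "text": f"tweet {i}",
                "created_at": "2020-03-01T10:00:00+00:00",
                "retweet_count": i,
                "favorite_count": 0,
                "user": {"id": 7, "followers_count": 5, "friends_count": 2,
                         "verified": False, "statuses_count": 10,
                         "created_at": "2015-06-01T00:00:00+00:00"},
            }
            for i in range(3)
        ]
        p.write_text("\n".join(json.dumps(x) for x in lines) + "\n")
        records = read_tweets(p)
        assert len(records) == 3
        assert records[0].user.followers_count == 5
        assert records[0].date == dt.date(2020, 3, 1)

    def test_malformed_line_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "t.jsonl"
        good = json.dumps({
            "id": 1, "text": "hi", "created_at": "2020-03-01T10:00:00+00:00",
            "user": {"id": 7},
        })
        p.write_text("\n".join([good] * 9 + ["{\"id\": 2}"]) + "\n")
        records = read_tweets(p)
        assert len(records) == 9

    def test_too_many_malformed_lines_is_an_error(self, tmp_path):
        p = tmp_path / "t.jsonl"
        p.write_text("not json\n" * 5 + "also bad\n")
        with pytest.raises(ValueError, match="malformed"):
            read_tweets(p)

    def test_twitter_v11_timestamp_format(self, tmp_path):
        p = tmp_path / "t.jsonl"
        p.write_text(json.dumps({
            "id": 1, "text": "hi", "created_at": "Wed Oct 10 20:19:24 +0000 2018",
            "user": {"id": 7},
        }) + "\n")
        (rec,) = read_tweets(p)
        assert rec.date == dt.date(2018, 10, 10)

    def test_round_trip_preserves_records(self, small_corpus, tmp_path):
        _, records, _, _ = small_corpus
        p = tmp_path / "corpus.jsonl"
        write_tweets(records, p)
        back = read_tweets(p)
        assert back == records


class TestWindowFilter:
    def test_inclusive_bounds(self):
        kept = _record("a", "u", 0, "x")
        last = TweetRecord(
            tweet_id="b", user=UserProfile(user_id="u"),
            created_at=dt.datetime(2020, 7, 7, 23, 59, tzinfo=UTC), text="x",
        )
        dropped = TweetRecord(
            tweet_id="c", user=UserProfile(user_id="u"),
            created_at=dt.datetime(2020, 7, 8, 0, 0, tzinfo=UTC), text="x",
        )
        assert window_filter([kept, last, dropped]) == [kept, last]

    def test_empty_input(self):
        assert window_filter([]) == []

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            window_filter([], dt.date(2020, 2, 1), dt.date(2020, 1, 1))


class TestLabelTweets:
    def test_single_match_gets_category(self, catalog):
        (rec,) = label_tweets([_record("a", "u", 3, "garlic fights coronavirus")], catalog)
        assert rec.labels == ("garlic",)
        assert rec.primary_myth == "garlic"
        assert rec.category == "Prevent"

    def test_multi_match_primary_is_catalog_order(self, catalog):
        (rec,) = label_tweets(
            [_record("a", "u", 3, "5g and mosquitos spread covid19")], catalog
        )
        assert set(rec.labels) == {"mosquitos", "5g_mobile_networks"}
        assert rec.primary_myth == "mosquitos"  # earlier Spread entry
        assert rec.category == "Spread"

    def test_non_matching_dropped(self, catalog):
        assert label_tweets([_record("a", "u", 0, "I love pasta")], catalog) == []

    def test_exclude_retweets_flag(self, catalog):
        rt = _record("a", "u", 0, "RT @x: garlic cures covid19")
        assert label_tweets([rt], catalog, exclude_retweets=True) == []
        assert len(label_tweets([rt], catalog)) == 1

    def test_synthetic_corpus_recovers_intended_myths(self, small_corpus, catalog):
        config, records, _, _ = small_corpus
        labeled = label_tweets(records, catalog)
        assert len(labeled) == len(records)
        assert all(r.category == config.category for r in labeled)


class TestBuildCascade:
    def test_repeat_user_counts_once(self, catalog):
        recs = label_tweets(
            [
                _record("a", "alice", 0, "garlic covid19"),
                _record("b", "alice", 3, "garlic covid19 again"),
            ],
            catalog,
        )
        c = build_cascade(recs, "Prevent", dt.date(2020, 1, 1), dt.date(2020, 1, 4))
        assert list(c.daily_new_users) == [1, 0, 0, 0]
        assert list(c.cumulative_users) == [1, 1, 1, 1]
        assert list(c.daily_new_tweets) == [1, 0, 0, 1]

    def test_hand_enumerated_two_days(self, catalog):
        recs = label_tweets(
            [
                _record("a", "u1", 0, "garlic covid19"),
                _record("b", "u2", 0, "garlic covid19"),
                _record("c", "u1", 0, "garlic covid19"),
                _record("d", "u3", 1, "garlic covid19"),
                _record("e", "u2", 1, "garlic covid19"),
            ],
            catalog,
        )
        c = build_cascade(recs, "Prevent", dt.date(2020, 1, 1), dt.date(2020, 1, 2))
        assert list(c.daily_new_users) == [2, 1]
        assert list(c.cumulative_users) == [2, 3]

    def test_absent_category_gives_zero_series(self, catalog):
        recs = label_tweets([_record("a", "u", 0, "garlic covid19")], catalog)
        c = build_cascade(recs, "Misc", dt.date(2020, 1, 1), dt.date(2020, 1, 5))
        assert c.n_days == 5
        assert c.total_users == 0
        assert not c.daily_new_tweets.any()

    def test_cascade_invariants_enforced(self):
        with pytest.raises(ValueError, match="cumsum"):
            Cascade(
                category="Misc",
                start_date=dt.date(2020, 1, 1),
                daily_new_tweets=np.array([1, 1]),
                daily_new_users=np.array([1, 1]),
                cumulative_users=np.array([1, 3]),
            )

    def test_ground_truth_cascade_round_trip(self, small_corpus, catalog, tmp_path):
        """synthesize -> write -> read -> label -> cascade equals ground truth."""
        config, records, _, truth = small_corpus
        p = tmp_path / "c.jsonl"
        write_tweets(records, p)
        labeled = label_tweets(read_tweets(p), catalog)
        end = config.start_date + dt.timedelta(days=config.T - 1)
        c = build_cascade(labeled, config.category, config.start_date, end)
        np.testing.assert_array_equal(c.daily_new_users, truth.new_infections)
        assert c.total_users == len(truth.infection_day)
        assert c.daily_new_tweets.sum() == len(records)


class TestCategoryShare:
    def test_share_partitions_labeled_records(self, labeled_small):
        out = category_tweet_share(labeled_small)
        assert out["n_tweets"].sum() == len(labeled_small)
        assert out["share"].sum() == pytest.approx(1.0)

    def test_packaged_reference_counts(self, catalog):
        from mythcast.catalog import summarize

        counts = summarize(catalog)["n_tweets"]
        out = category_tweet_share(counts)
        assert out.loc["Spread", "n_tweets"] == 86198
        assert out.loc["Spread", "share"] > 0.5

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            category_tweet_share({"Prevent": 0})
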