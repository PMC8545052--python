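"""Archived-tweet store: JSONL parsing, date filtering, myth labeling, cascades.

Records follow Twitter v1.1-style field names (a small subset). A *cascade*
for one myth category is the daily series of new tweets and of new distinct
users — a user counts once, on the day of their first tweet in the category —
plus the running cumulative distinct-user count. The cumulative distinct-user
series is what the SIR diffusion model is fitted to: the infected-plus-
recovered compartment is read as "users who have posted at least one tweet
on the myth".
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, MythCatalog, match

__all__ = [
    "UserProfile",
    "TweetRecord",
    "Cascade",
    "read_tweets",
    "write_tweets",
    "window_filter",
    "label_tweets",
    "build_cascade",
    "category_tweet_share",
    "DEFAULT_START",
    "DEFAULT_END",
]

log = logging.getLogger(__name__)

#: Default observation window (inclusive).
DEFAULT_START = dt.date(2020, 1, 1)
DEFAULT_END = dt.date(2020, 7, 7)

_TWITTER_TS = "%a %b %d %H:%M:%S %z %Y"  # e.g. "Wed Oct 10 20:19:24 +0000 2018"


def _parse_ts(value: str | int | float) -> dt.datetime:
    """Parse an ISO-8601 or Twitter-v1.1 timestamp to an aware UTC datetime."""
    if isinstance(value, (int, float)):
        return dt.datetime.fromtimestamp(float(value), tz=dt.timezone.utc)
    try:
        parsed = dt.datetime.fromisoformat(str(value))
    except ValueError:
        parsed = dt.datetime.strptime(str(value), _TWITTER_TS)
    if parsed.tzinfo is None:
        parsed = parsed.replace(tzinfo=dt.timezone.utc)
    return parsed.astimezone(dt.timezone.utc)


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    followers_count: int = 0
    followees_count: int = 0
    verified: bool = False
    statuses_count: int = 0
    created_at: dt.date | None = None

    def __post_init__(self) -> None:
        for name in ("followers_count", "followees_count", "statuses_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TweetRecord:
    tweet_id: str
    user: UserProfile
    created_at: dt.datetime
    text: str
    retweet_count: int = 0
    favorite_count: int = 0
    # set by label_tweets
    labels: tuple[str, ...] = ()
    primary_myth: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.retweet_count < 0 or self.favorite_count < 0:
            raise ValueError("engagement counts must be >= 0")

    @property
    def date(self) -> dt.date:
        return self.created_at.astimezone(dt.timezone.utc).date()


@dataclass(frozen=True)
class Cascade:
    """Daily tweet/user series for one myth category over a date window."""

    category: str
    start_date: dt.date
    daily_new_tweets: np.ndarray
    daily_new_users: np.ndarray
    cumulative_users: np.ndarray

    def __post_init__(self) -> None:
        t, u, c = (
            np.asarray(self.daily_new_tweets),
            np.asarray(self.daily_new_users),
            np.asarray(self.cumulative_users),
        )
        if not (len(t) == len(u) == len(c)):
            raise ValueError("series lengths differ")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative_users must be non-decreasing")
        if not np.array_equal(np.cumsum(u), c):
            raise ValueError("cumulative_users must be the cumsum of daily_new_users")

    @property
    def n_days(self) -> int:
        return len(self.daily_new_tweets)

    @property
    def total_users(self) -> int:
        return int(self.cumulative_users[-1]) if self.n_days else 0

    def to_frame(self) -> pd.DataFrame:
        dates = [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]
        return pd.DataFrame(
            {
                "date": dates,
                "daily_new_tweets": np.asarray(self.daily_new_tweets, dtype=int),
                "daily_new_users": np.asarray(self.daily_new_users, dtype=int),
                "cumulative_users": np.asarray(self.cumulative_users, dtype=int),
            }
        )


def _record_from_json(obj: dict) -> TweetRecord:
    user = obj["user"]
    created = user.get("created_at")
    return TweetRecord(
        tweet_id=str(obj["id"]),
        user=UserProfile(
            user_id=str(user["id"]),
            followers_count=int(user.get("followers_count", 0)),
            followees_count=int(user.get("friends_count", 0)),
            verified=bool(user.get("verified", False)),
            statuses_count=int(user.get("statuses_count", 0)),
            created_at=_parse_ts(created).date() if created is not None else None,
        ),
        created_at=_parse_ts(obj["created_at"]),
        text=str(obj["text"]),
        retweet_count=int(obj.get("retweet_count", 0)),
        favorite_count=int(obj.get("favorite_count", 0)),
    )


def read_tweets(path, *, max_malformed_frac: float = 0.10) -> list[TweetRecord]:
    """Read a JSON Lines tweet archive.

    Malformed lines (bad JSON or missing required fields) are skipped with a
    warning; if they exceed ``max_malformed_frac`` of all non-empty lines a
    ``ValueError`` is raised.
    """
    records: list[TweetRecord] = []
    bad = 0
    total = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            total += 1
            try:
                records.append(_record_from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as err:
                bad += 1
                log.warning("skipping malformed line %d of %s: %s", lineno, path, err)
    if total and bad / total > max_malformed_frac:
        raise ValueError(
            f"{bad}/{total} malformed lines in {path} "
            f"(> {max_malformed_frac:.0%} allowed)"
        )
    log.info("read %d tweet records from %s (%d malformed skipped)", len(records), path, bad)
    return records


def write_tweets(records, path) -> None:
    """Write records as the JSON Lines dialect :func:`read_tweets` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "id": r.tweet_id,
                "text": r.text,
                "created_at": r.created_at.astimezone(dt.timezone.utc).isoformat(),
                "retweet_count": int(r.retweet_count),
                "favorite_count": int(r.favorite_count),
                "user": {
                    "id": r.user.user_id,
                    "followers_count": int(r.user.followers_count),
                    "friends_count": int(r.user.followees_count),
                    "verified": bool(r.user.verified),
                    "statuses_count": int(r.user.statuses_count),
                    "created_at": r.user.created_at.isoformat()
                    if r.user.created_at
                    else None,
                },
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def window_filter(
    records,
    start_date: dt.date = DEFAULT_START,
    end_date: dt.date = DEFAULT_END,
) -> list[TweetRecord]:
    """Keep records whose UTC date lies in [start_date, end_date] inclusive."""
    if start_date > end_date:
        raise ValueError(f"start_date {start_date} after end_date {end_date}")
    return [r for r in records if start_date <= r.date <= end_date]


def label_tweets(
    records,
    catalog: MythCatalog,
    *,
    exclude_retweets: bool = False,
    token_boundary: bool = False,
) -> list[TweetRecord]:
    """Label records with matching myths; drop records matching none.

    Every matching myth_id is retained in ``labels``; the *primary* myth is
    the earliest matching entry in catalog order and determines the record's
    category (so per-category counts partition the labeled corpus).
    """
    queries = catalog.queries()
    order = [e.myth_id for e in catalog.entries]
    out: list[TweetRecord] = []
    for r in records:
        if exclude_retweets and r.text.startswith("RT @"):
            continue
        hits = tuple(
            mid for mid in order if match(r.text, queries[mid], token_boundary=token_boundary)
        )
        if not hits:
            continue
        primary = hits[0]
        out.append(
            replace(
                r,
                labels=hits,
                primary_myth=primary,
                category=catalog.get(primary).category,
            )
        )
    log.info("labeled %d/%d records", len(out), len(records))
    return out


def build_cascade(
    labeled,
    category: str,
    start_date: dt.date = DEFAULT_START,
    end_date: dt.date = DEFAULT_END,
    *,
    by: str = "primary",
) -> Cascade:
    """Build the daily cascade for one category from labeled records.

    ``by="primary"`` uses each record's primary category (partition);
    ``by="any"`` includes records whose label set touches the category.
    An absent category yields all-zero series, not an error.
    """
    if start_date > end_date:
        raise ValueError("invalid window")
    n_days = (end_date - start_date).days + 1
    tweets = np.zeros(n_days, dtype=int)
    new_users = np.zeros(n_days, dtype=int)
    seen: set[str] = set()

    if by == "any":
        # a label's category is fixed by the catalog; recover it from any
        # record where that label is primary
        cat_of: dict[str, str] = {
            r.primary_myth: r.category for r in labeled if r.primary_myth is not None
        }
        selected = [
            r
            for r in labeled
            if r.category == category
            or any(cat_of.get(lbl) == category for lbl in r.labels)
        ]
    else:
        selected = [r for r in labeled if r.category == category]

    for r in sorted(selected, key=lambda r: (r.created_at, r.tweet_id)):
        day = (r.date - start_date).days
        if not 0 <= day < n_days:
            continue
        tweets[day] += 1
        if r.user.user_id not in seen:
            seen.add(r.user.user_id)
            new_users[day] += 1
    return Cascade(
        category=category,
        start_date=start_date,
        daily_new_tweets=tweets,
        daily_new_users=new_users,
        cumulative_users=np.cumsum(new_users),
    )


def category_tweet_share(source) -> pd.DataFrame:
    """Per-category tweet counts and shares.

    ``source`` is either a list of labeled records (partitioned by primary
    category) or a mapping/Series of per-category tweet counts (e.g. the
    packaged reference table sums).
    """
    if isinstance(source, (dict, pd.Series)):
        counts = pd.Series(source, dtype=float)
    else:
        counts = pd.Series(
            [r.category for r in source if r.category is not None]
        ).value_counts()
    counts = counts.reindex(CATEGORIES, fill_value=0).astype(int)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no labeled tweets to summarize")
    return pd.DataFrame({"n_tweets": counts, "share": counts / total})
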