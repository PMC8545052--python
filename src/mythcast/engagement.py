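"""Engagement summaries: user metadata, tweet reactions, tail diagnostics.

Per-category descriptive statistics of the users who participated in a
myth's cascade (followers, followees, verified status, lifetime posted
statuses as an engagement proxy, account age) and of the tweets' reaction
counts (retweets, favorites). Count-like user features are summarised on a
log scale, ``log(1 + x)``, to tame their heavy tails; reaction counts are
summarised on the raw scale. The reaction-count distribution itself is
exported as a log-binned histogram plus empirical CCDF, with a Hill
estimator of the tail index over the upper order statistics.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CategoryUserSummary",
    "CategoryReactionSummary",
    "user_meta_summary",
    "reaction_summary",
    "engagement_distribution",
    "hill_estimator",
]

_LOG_FEATURES = ("followers", "followees", "engagement", "account_age")


@dataclass(frozen=True)
class CategoryUserSummary:
    """Log-scale mean/std of user metadata for one category (users deduplicated)."""

    category: str
    n_users: int
    mean_log: dict[str, float]
    std_log: dict[str, float]
    verified_count: int
    verified_proportion: float
    log_base: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_log": pd.Series(self.mean_log),
                "std_log": pd.Series(self.std_log),
            }
        )


@dataclass(frozen=True)
class CategoryReactionSummary:
    category: str
    n_tweets: int
    mean_retweets: float
    std_retweets: float
    mean_favorites: float
    std_favorites: float


def _distinct_users(labeled, category: str):
    seen = {}
    for r in labeled:
        if r.category == category and r.user.user_id not in seen:
            seen[r.user.user_id] = r.user
    return list(seen.values())


def user_meta_summary(
    labeled,
    category: str,
    log_base: float = math.e,
    summary_date: dt.date | None = None,
) -> CategoryUserSummary:
    """Log-scale user-metadata summary for one category.

    Each distinct user counts once. Features are transformed as
    ``log_base(1 + x)``; account age is days between the user's account
    creation and ``summary_date`` (default: today). Verified status is
    summarised as a count and proportion rather than on a log scale.
    """
    users = _distinct_users(labeled, category)
    if not users:
        raise ValueError(f"no users in category {category!r}")
    if summary_date is None:
        summary_date = dt.date.today()
    denom = math.log(log_base)
    feats = {
        "followers": np.array([u.followers_count for u in users], dtype=float),
        "followees": np.array([u.followees_count for u in users], dtype=float),
        "engagement": np.array([u.statuses_count for u in users], dtype=float),
        "account_age": np.array(
            [
                max((summary_date - u.created_at).days, 0) if u.created_at else 0
                for u in users
            ],
            dtype=float,
        ),
    }
    mean_log, std_log = {}, {}
    for name in _LOG_FEATURES:
        lx = np.log1p(feats[name]) / denom
        mean_log[name] = float(lx.mean())
        std_log[name] = float(lx.std(ddof=0))
    n_verified = sum(1 for u in users if u.verified)
    return CategoryUserSummary(
        category=category,
        n_users=len(users),
        mean_log=mean_log,
        std_log=std_log,
        verified_count=n_verified,
        verified_proportion=n_verified / len(users),
        log_base=float(log_base),
    )


def reaction_summary(labeled, category: str) -> CategoryReactionSummary:
    """Raw-scale mean/std of retweet and favorite counts over tweets."""
    rts = np.array(
        [r.retweet_count for r in labeled if r.category == category], dtype=float
    )
    favs = np.array(
        [r.favorite_count for r in labeled if r.category == category], dtype=float
    )
    if rts.size == 0:
        raise ValueError(f"no tweets in category {category!r}")
    return CategoryReactionSummary(
        category=category,
        n_tweets=int(rts.size),
        mean_retweets=float(rts.mean()),
        std_retweets=float(rts.std(ddof=0)),
        mean_favorites=float(favs.mean()),
        std_favorites=float(favs.std(ddof=0)),
    )


def hill_estimator(values: np.ndarray, tail_fraction: float = 0.01) -> float:
    """Hill estimate of the Pareto tail index over the top ``tail_fraction``.

    For order statistics X(1) >= ... >= X(k) above the threshold X(k+1),
    alpha_hat = k / sum_i log(X(i) / X(k+1)).
    """
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if x.size < 10:
        raise ValueError("need at least 10 positive values")
    k = max(int(np.floor(x.size * tail_fraction)), 2)
    xs = np.sort(x)[::-1]
    threshold = xs[k]
    if threshold <= 0:
        raise ValueError("tail threshold is not positive")
    logs = np.log(xs[:k] / threshold)
    return float(k / logs.sum())


def engagement_distribution(
    labeled,
    category: str,
    metric: str = "retweet_count",
    n_bins: int = 30,
    tail_fraction: float = 0.01,
) -> dict:
    """Log-binned histogram + empirical CCDF of a reaction metric.

    Returns a dict with ``bin_edges``, ``bin_counts``, ``ccdf_x``,
    ``ccdf_y`` (P(X >= x) over the distinct observed values, starting at 1)
    and a ``tail_ratio`` heaviness statistic (99th percentile / median).
    A Hill tail-index estimate is included when enough positive mass exists.
    """
    if metric not in ("retweet_count", "favorite_count"):
        raise ValueError("metric must be retweet_count or favorite_count")
    x = np.array(
        [getattr(r, metric) for r in labeled if r.category == category], dtype=float
    )
    if x.size == 0:
        raise ValueError(f"no tweets in category {category!r}")
    if np.all(x == 0):
        warnings.warn(f"all-zero {metric} in {category}; degenerate distribution")
        return {
            "category": category,
            "metric": metric,
            "bin_edges": np.array([0.0, 1.0]),
            "bin_counts": np.array([x.size]),
            "ccdf_x": np.array([0.0]),
            "ccdf_y": np.array([1.0]),
            "tail_ratio": float("nan"),
            "hill_alpha": float("nan"),
        }
    top = x.max()
    edges = np.concatenate(([0.0], np.logspace(0, np.log10(top + 1), n_bins)))
    counts, _ = np.histogram(x, bins=edges)
    xv = np.sort(np.unique(x))
    ccdf = np.array([(x >= v).mean() for v in xv])
    median = float(np.median(x))
    p99 = float(np.percentile(x, 99))
    try:
        alpha = hill_estimator(x, tail_fraction)
    except ValueError:
        alpha = float("nan")
    return {
        "category": category,
        "metric": metric,
        "bin_edges": edges,
        "bin_counts": counts,
        "ccdf_x": xv,
        "ccdf_y": ccdf,
        "tail_ratio": p99 / median if median > 0 else float("inf"),
        "hill_alpha": alpha,
    }
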