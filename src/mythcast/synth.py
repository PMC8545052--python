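"""Synthetic tweet-corpus generator with known SIR ground truth.

Emulates the statistical structure of a myth-tweet corpus so that the whole
pipeline can be exercised and validated against a known answer:

* daily first-posting-user cascades follow a discrete-day stochastic SIR
  (chain-binomial / Reed-Frost with exponential exposure), so the true
  (beta, gamma, R0) behind every cascade is known;
* tweet texts embed one myth's keyword phrase(s) plus one pandemic keyword
  plus neutral filler words, so keyword labeling recovers the intended myth
  with certainty;
* retweet/favorite/follower counts are drawn log-normal (heavy "long tail");
* per-tweet six-class emotion probability vectors are drawn from a Dirichlet
  with a configurable, fear-dominant mean.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import MythCatalog
from .store import TweetRecord, UserProfile, write_tweets

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "FILLER_VOCAB",
    "DEFAULT_EMOTION_MEAN",
    "simulate_chain_binomial",
    "synthesize_corpus",
    "write_corpus",
    "demo_configs",
]

#: Fear-dominant mean emotion vector (anger, disgust, fear, joy, sadness,
#: surprise): fear 0.55 and joy 0.25 dominate, the rest are minor.
DEFAULT_EMOTION_MEAN = (0.09, 0.03, 0.55, 0.25, 0.04, 0.04)

#: Neutral filler words; deliberately disjoint from all catalog keyword and
#: pandemic-keyword substrings so filler can never create a spurious match.
FILLER_VOCAB = (
    "today", "really", "just", "think", "folks", "saying", "heard", "friend",
    "news", "read", "online", "sharing", "share", "true", "believe", "crazy",
    "wow", "everyone", "telling", "story", "post", "thread", "look", "video",
    "claim", "apparently", "media", "report", "seen", "morning", "night",
    "week", "again", "please", "stop", "spreading", "rumour", "going",
    "around", "neighbour", "family", "group", "chat", "message", "forward",
    "reading", "article", "link", "checked", "actually", "maybe", "honestly",
    "update", "watch", "listen", "radio", "show", "talk", "town", "city",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give a moderately supercritical cascade.

    Rates are per day. ``posting_rate`` is the expected number of extra
    tweets an infectious user posts on each day after their infection day.
    Engagement and follower counts are log-normal with the given natural-log
    (mu, sigma). ``emotion_mean`` must sum to 1.
    """

    N: int = 10_000
    beta: float = 0.4
    gamma: float = 0.2
    T: int = 120
    i0: int = 10
    seed: int = 0
    category: str = "Spread"
    start_date: dt.date = dt.date(2020, 1, 1)
    posting_rate: float = 0.3
    emotion_mean: tuple[float, ...] = DEFAULT_EMOTION_MEAN
    emotion_concentration: float = 20.0
    retweet_lognorm: tuple[float, float] = (0.0, 2.0)
    favorite_lognorm: tuple[float, float] = (1.0, 2.0)
    followers_lognorm: tuple[float, float] = (8.0, 2.0)
    followees_lognorm: tuple[float, float] = (6.0, 1.5)
    statuses_lognorm: tuple[float, float] = (8.0, 2.0)
    verified_prob: float = 0.02
    vocab: tuple[str, ...] = FILLER_VOCAB
    #: prepended to user/tweet ids so corpora for different categories can
    #: be concatenated without id collisions
    id_prefix: str = ""

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 1 <= self.i0 < self.N:
            raise ValueError("need 1 <= i0 < N")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if abs(sum(self.emotion_mean) - 1.0) > 1e-9 or len(self.emotion_mean) != 6:
            raise ValueError("emotion_mean must be 6 probabilities summing to 1")
        if self.posting_rate < 0:
            raise ValueError("posting_rate must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True generator parameters and the realised epidemic path."""

    beta: float
    gamma: float
    N: int
    i0: int
    new_infections: np.ndarray  # day 0 holds the i0 seeds
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    infection_day: dict[str, int] = field(default_factory=dict)

    @property
    def r0(self) -> float:
        if self.gamma == 0:
            return float("inf")
        return self.beta / self.gamma

    def to_json(self) -> str:
        obj = {
            "beta": self.beta,
            "gamma": self.gamma,
            "r0": None if np.isinf(self.r0) else self.r0,
            "N": self.N,
            "i0": self.i0,
            "new_infections": np.asarray(self.new_infections).astype(int).tolist(),
            "S": np.asarray(self.S).astype(int).tolist(),
            "I": np.asarray(self.I).astype(int).tolist(),
            "R": np.asarray(self.R).astype(int).tolist(),
            "infection_day": self.infection_day,
        }
        return json.dumps(obj, sort_keys=True)


def simulate_chain_binomial(
    beta: float,
    gamma: float,
    N: int,
    T: int,
    i0: int,
    seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Discrete-day stochastic SIR (chain-binomial with exponential exposure).

    Each day, every susceptible is infected with probability
    ``1 - exp(-beta * I_t / N)`` and every infectious individual recovers
    with probability ``1 - exp(-gamma)``; S+I+R = N on every day.
    """
    if beta <= 0 or gamma < 0 or not 1 <= i0 < N or T < 2:
        raise ValueError("invalid chain-binomial parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = np.empty(T, dtype=int)
    I = np.empty(T, dtype=int)
    R = np.empty(T, dtype=int)
    new = np.zeros(T, dtype=int)
    s, i, r = N - i0, i0, 0
    S[0], I[0], R[0] = s, i, r
    new[0] = i0
    p_rec = 1.0 - np.exp(-gamma)
    for t in range(1, T):
        p_inf = 1.0 - np.exp(-beta * i / N)
        n_new = int(rng.binomial(s, p_inf)) if s > 0 else 0
        n_rec = int(rng.binomial(i, p_rec)) if i > 0 else 0
        s -= n_new
        i += n_new - n_rec
        r += n_rec
        S[t], I[t], R[t] = s, i, r
        new[t] = n_new
    assert np.all(S + I + R == N)
    return GroundTruth(beta=beta, gamma=gamma, N=N, i0=i0, new_infections=new, S=S, I=I, R=R)


def _check_vocab(config: SynthConfig, catalog: MythCatalog) -> None:
    phrases = [k.casefold() for e in catalog.entries for k in e.keywords]
    phrases += [c.casefold() for c in catalog.covid_keywords]
    for w in config.vocab:
        wl = w.casefold()
        for p in phrases:
            if p in wl or wl in p:
                raise ValueError(
                    f"filler word {w!r} collides with catalog phrase {p!r}"
                )


def synthesize_corpus(
    config: SynthConfig, catalog: MythCatalog
) -> tuple[list[TweetRecord], pd.DataFrame, GroundTruth]:
    """Generate a labeled-by-construction corpus for one myth category.

    Returns (records, per-tweet emotion table, ground truth). Every newly
    infected user posts exactly one tweet on their infection day (so the
    cascade's daily new-user series equals the true new-infection series),
    plus Poisson(posting_rate) tweets on each later day while infectious.
    """
    _check_vocab(config, catalog)
    entries = [e for e in catalog.entries if e.category == config.category]
    if not entries:
        raise ValueError(f"catalog has no myths in category {config.category!r}")
    rng = np.random.default_rng(config.seed)

    # per-user stochastic SIR so infectious periods are known per user
    uid = 0
    infectious: list[int] = []  # user indices
    infection_day: dict[int, int] = {}
    recovery_day: dict[int, int] = {}
    s = config.N - config.i0
    S = np.empty(config.T, dtype=int)
    I = np.empty(config.T, dtype=int)
    R = np.empty(config.T, dtype=int)
    new = np.zeros(config.T, dtype=int)
    p_rec = 1.0 - np.exp(-config.gamma)
    n_rec_total = 0
    for t in range(config.T):
        if t == 0:
            n_new = config.i0
        else:
            p_inf = 1.0 - np.exp(-config.beta * len(infectious) / config.N)
            n_new = int(rng.binomial(s, p_inf)) if s > 0 else 0
            s -= n_new
            n_rec = int(rng.binomial(len(infectious), p_rec)) if infectious else 0
            if n_rec:
                idx = rng.choice(len(infectious), size=n_rec, replace=False)
                for j in sorted(idx, reverse=True):
                    recovery_day[infectious[j]] = t
                    infectious.pop(j)
                n_rec_total += n_rec
        for _ in range(n_new):
            infection_day[uid] = t
            infectious.append(uid)
            uid += 1
        new[t] = n_new
        S[t], I[t], R[t] = s, len(infectious), n_rec_total
    assert np.all(S + I + R == config.N)

    # user metadata
    n_users = uid
    followers = np.floor(
        rng.lognormal(*config.followers_lognorm, size=n_users)
    ).astype(int)
    followees = np.floor(
        rng.lognormal(*config.followees_lognorm, size=n_users)
    ).astype(int)
    statuses = np.floor(rng.lognormal(*config.statuses_lognorm, size=n_users)).astype(int)
    verified = rng.random(n_users) < config.verified_prob
    acct_age_days = rng.integers(400, 4000, size=n_users)  # well before the window
    myth_of_user = rng.integers(0, len(entries), size=n_users)

    def make_text(u: int) -> str:
        entry = entries[myth_of_user[u]]
        if entry.mode == "OR":
            kw = [entry.keywords[rng.integers(0, len(entry.keywords))]]
        else:
            kw = list(entry.keywords)
        covid = catalog.covid_keywords[rng.integers(0, len(catalog.covid_keywords))]
        n_fill = int(rng.integers(3, 9))
        fill = list(rng.choice(config.vocab, size=n_fill))
        cut = int(rng.integers(0, n_fill + 1))
        words = fill[:cut] + kw + [covid] + fill[cut:]
        return " ".join(words)

    records: list[TweetRecord] = []
    emotions_rows: list[list] = []
    users: dict[int, UserProfile] = {}
    tid = 0
    alpha = config.emotion_concentration * np.asarray(config.emotion_mean)

    def emit(u: int, day: int) -> None:
        nonlocal tid
        if u not in users:
            users[u] = UserProfile(
                user_id=f"{config.id_prefix}u{u:06d}",
                followers_count=int(followers[u]),
                followees_count=int(followees[u]),
                verified=bool(verified[u]),
                statuses_count=int(statuses[u]),
                created_at=config.start_date - dt.timedelta(days=int(acct_age_days[u])),
            )
        second = int(rng.integers(0, 86_400))
        ts = dt.datetime.combine(
            config.start_date + dt.timedelta(days=day),
            dt.time(second // 3600, (second // 60) % 60, second % 60),
            tzinfo=dt.timezone.utc,
        )
        rec = TweetRecord(
            tweet_id=f"{config.id_prefix}t{tid:07d}",
            user=users[u],
            created_at=ts,
            text=make_text(u),
            retweet_count=int(np.floor(rng.lognormal(*config.retweet_lognorm))),
            favorite_count=int(np.floor(rng.lognormal(*config.favorite_lognorm))),
        )
        records.append(rec)
        emotions_rows.append([rec.tweet_id, *rng.dirichlet(alpha)])
        tid += 1

    for u in range(n_users):
        day0 = infection_day[u]
        emit(u, day0)
        end = recovery_day.get(u, config.T)
        for day in range(day0 + 1, min(end, config.T)):
            for _ in range(int(rng.poisson(config.posting_rate))):
                emit(u, day)

    emotions = pd.DataFrame(
        emotions_rows,
        columns=["tweet_id", "anger", "disgust", "fear", "joy", "sadness", "surprise"],
    )
    truth = GroundTruth(
        beta=config.beta,
        gamma=config.gamma,
        N=config.N,
        i0=config.i0,
        new_infections=new,
        S=S,
        I=I,
        R=R,
        infection_day={f"{config.id_prefix}u{u:06d}": int(d) for u, d in infection_day.items()},
    )
    return records, emotions, truth


def write_corpus(records, emotions: pd.DataFrame, truth: GroundTruth, out_dir) -> dict:
    """Write corpus.jsonl, emotions.csv and ground_truth.json under out_dir."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = out / "corpus.jsonl"
    write_tweets(records, corpus)
    emo = out / "emotions.csv"
    emotions.to_csv(emo, index=False, float_format="%.10f")
    gt = out / "ground_truth.json"
    gt.write_text(truth.to_json() + "\n", encoding="utf-8")
    return {"corpus": str(corpus), "emotions": str(emo), "ground_truth": str(gt)}


def demo_configs(seed: int = 0, scale: float = 1.0) -> dict[str, SynthConfig]:
    """One generator config per category for end-to-end demo runs.

    Transmission rates differ by category (Detect below the infodemic threshold,
    the rest above it); population sizes are modest so a full
    report run stays fast. ``scale`` multiplies the population sizes.
    """
    base = dict(T=120, gamma=0.2, i0=10, posting_rate=0.3)
    specs = {
        "Prevent": dict(beta=0.538, N=4000),
        "Spread": dict(beta=0.46, N=6000),
        "Detect": dict(beta=0.16, N=3000, i0=30),
        "Treat": dict(beta=0.32, N=3000),
        "Misc": dict(beta=0.55, gamma=0.05, N=2000, i0=3),
    }
    out = {}
    for k, (cat, spec) in enumerate(specs.items()):
        kwargs = {**base, **spec}
        kwargs["N"] = max(200, int(kwargs["N"] * scale))
        out[cat] = SynthConfig(category=cat, seed=seed + 1000 * k, id_prefix=cat[:2].lower() + "_", **kwargs)
    return out
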