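"""Per-category topic tables: tokenizing, Porter stemming, top-k terms.

For each myth category the most frequent stems are tabulated after
stripping URLs, mentions and hashtag markers, removing English stop words,
stemming with the Porter algorithm, and excluding the pandemic keywords
themselves (so the table shows the *discussed topics*, not the search
terms). The display convention is k named terms plus one "other" bucket;
tweet-level proportions assign each tweet to the highest-ranked named stem
it contains, or to "other".
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import PorterStemmer, porter_stem
from .catalog import COVID_KEYWORDS

__all__ = [
    "TermTable",
    "tokenize",
    "porter_stem",
    "default_exclusions",
    "top_terms",
    "term_tweet_proportions",
]

_URL = re.compile(r"(?:https?://\S+|www\.\S+)")
_MENTION = re.compile(r"@\w+")
_SPLIT = re.compile(r"[^0-9a-z]+")

OTHER = "other"


def tokenize(text: str) -> list[str]:
    """Lowercase, strip URLs/@mentions, drop '#', split on non-alphanumerics.

    Tokens shorter than two characters are discarded.
    """
    t = text.lower()
    t = _URL.sub(" ", t)
    t = _MENTION.sub(" ", t)
    t = t.replace("#", "")
    return [tok for tok in _SPLIT.split(t) if len(tok) >= 2]


def default_exclusions() -> frozenset[str]:
    """Stems of the pandemic keywords, excluded from every term table."""
    stems = set()
    for kw in COVID_KEYWORDS:
        for tok in tokenize(kw):
            stems.add(porter_stem(tok))
    return frozenset(stems)


@dataclass(frozen=True)
class TermTable:
    """Ranked top stems for one category, with an "other" bucket."""

    category: str
    terms: tuple[tuple[str, int], ...]  # (stem, frequency), rank order
    k: int
    other_frequency: int
    proportions: tuple[tuple[str, float], ...] = ()  # includes ("other", p)

    def __post_init__(self) -> None:
        freqs = [f for _, f in self.terms]
        if any(b > a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be non-increasing down the ranking")

    @property
    def stems(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.terms)

    def to_frame(self) -> pd.DataFrame:
        props = dict(self.proportions)
        rows = [
            {
                "rank": i + 1,
                "stem": s,
                "frequency": f,
                "tweet_proportion": props.get(s),
            }
            for i, (s, f) in enumerate(self.terms)
        ]
        rows.append(
            {
                "rank": len(self.terms) + 1,
                "stem": OTHER,
                "frequency": self.other_frequency,
                "tweet_proportion": props.get(OTHER),
            }
        )
        return pd.DataFrame(rows)


def _stems_of(text: str, stemmer, stop_words: frozenset[str] | None) -> list[str]:
    toks = tokenize(text)
    if stop_words:
        toks = [t for t in toks if t not in stop_words]
    return [stemmer(t) for t in toks]


def top_terms(
    labeled,
    category: str,
    k: int = 14,
    exclusions: frozenset[str] | None = None,
    *,
    remove_stop_words: bool = True,
) -> TermTable:
    """Top-k stems by token-occurrence frequency in one category's tweets.

    Ties are broken lexicographically; the remaining token mass is reported
    as the "other" bucket, giving k+1 display rows. ``exclusions`` default
    to the stemmed pandemic keywords.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if exclusions is None:
        exclusions = default_exclusions()
    texts = [r.text for r in labeled if r.category == category]
    if not texts:
        raise ValueError(f"no tweets in category {category!r}")
    stop = frozenset(ENGLISH_STOP_WORDS) if remove_stop_words else None
    stemmer = PorterStemmer()
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(s for s in _stems_of(text, stemmer, stop) if s not in exclusions)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = tuple(ranked[:k])
    other = sum(f for _, f in ranked[k:])
    table = TermTable(category=category, terms=top, k=k, other_frequency=other)
    props = term_tweet_proportions(labeled, table, remove_stop_words=remove_stop_words)
    return TermTable(
        category=category,
        terms=top,
        k=k,
        other_frequency=other,
        proportions=tuple(props.items()),
    )


def term_tweet_proportions(
    labeled,
    table: TermTable,
    *,
    remove_stop_words: bool = True,
    assignment: str = "highest_rank",
) -> dict[str, float]:
    """Tweet-level proportions for a term table's stems plus "other".

    With ``assignment="highest_rank"`` (default) each tweet counts once,
    toward the highest-ranked named stem it contains or toward "other", so
    the proportions partition and sum to 1. ``assignment="any"`` instead
    reports, for each stem, the (overlapping) fraction of tweets containing
    it, with "other" still the fraction containing none.
    """
    texts = [r.text for r in labeled if r.category == table.category]
    if not texts:
        raise ValueError(f"no tweets in category {table.category!r}")
    stop = frozenset(ENGLISH_STOP_WORDS) if remove_stop_words else None
    stemmer = PorterStemmer()
    ranked = table.stems
    counts = {s: 0 for s in ranked}
    other = 0
    for text in texts:
        present = set(_stems_of(text, stemmer, stop))
        hits = [s for s in ranked if s in present]
        if assignment == "any":
            for s in hits:
                counts[s] += 1
            if not hits:
                other += 1
        else:
            if hits:
                counts[hits[0]] += 1
            else:
                other += 1
    n = len(texts)
    out = {s: c / n for s, c in counts.items()}
    out[OTHER] = other / n
    return out
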