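"""WHO Mythbuster catalog: myth entries, keyword queries, and text matching.

The catalog transcribes the 27 widely circulated COVID-19 myths tracked by
the WHO Mythbusters page (as of 7 July 2020), each with its keyword
phrase(s) and one of five categories: Prevent, Spread, Detect, Treat, Misc.
A tweet is considered to be about a myth when its text contains the myth's
keyword phrase(s) together with at least one generic pandemic keyword
("covid19", "coronavirus", ...), mirroring the boolean search queries used
to collect such corpora, e.g.::

    garlic AND (covid19 OR covid-19 OR corona virus OR coronavirus
                OR 2019-nCoV OR 2019nCoV)

Matching is case-insensitive substring containment on whitespace-normalised
text by default; a token-boundary mode is available for stricter matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "COVID_KEYWORDS",
    "MythEntry",
    "MythCatalog",
    "QueryExpression",
    "load_catalog",
    "build_query",
    "match",
    "summarize",
]

#: The five myth categories.
CATEGORIES = ("Prevent", "Spread", "Detect", "Treat", "Misc")

#: Generic pandemic keywords combined (OR) with each myth's keywords.
COVID_KEYWORDS = (
    "covid19",
    "covid-19",
    "corona virus",
    "coronavirus",
    "2019-nCoV",
    "2019nCoV",
)

_WS = re.compile(r"\s+")


def _normalize(text: str) -> str:
    """Case-fold and collapse runs of whitespace to single spaces."""
    return _WS.sub(" ", text.casefold()).strip()


class CatalogError(ValueError):
    """Raised for invalid catalog files or entries."""


@dataclass(frozen=True)
class MythEntry:
    """One myth: an id slug, its keyword phrase(s) and its category.

    ``mode`` says how multiple keyword phrases combine: ``"AND"`` (a text
    must contain every phrase, e.g. "Masks" and "CO2 intoxication") or
    ``"OR"`` (alternative namings of one concept, e.g. "Bleach" /
    "Disinfectant").
    """

    myth_id: str
    keywords: tuple[str, ...]
    category: str
    mode: str = "AND"
    n_tweets: int | None = None
    n_users: int | None = None

    def __post_init__(self) -> None:
        if not self.myth_id:
            raise CatalogError("myth_id must be non-empty")
        if not self.keywords or any(not k.strip() for k in self.keywords):
            raise CatalogError(f"myth {self.myth_id!r}: keywords must be non-empty")
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"myth {self.myth_id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.mode not in ("AND", "OR"):
            raise CatalogError(f"myth {self.myth_id!r}: mode must be AND or OR")


@dataclass(frozen=True)
class QueryExpression:
    """A boolean keyword query: myth phrases plus pandemic-keyword alternatives.

    A text matches iff it contains the myth phrases (all of them when
    ``require_all``, at least one otherwise) AND at least one of the
    ``covid_terms``, after case folding and whitespace normalisation.
    """

    myth_terms: tuple[str, ...]
    covid_terms: tuple[str, ...]
    require_all: bool = True

    def __post_init__(self) -> None:
        if not self.myth_terms:
            raise CatalogError("query needs at least one myth term")
        if not self.covid_terms:
            raise CatalogError("query needs at least one covid term")


@dataclass(frozen=True)
class MythCatalog:
    """An ordered collection of :class:`MythEntry` plus the pandemic keywords."""

    entries: tuple[MythEntry, ...]
    covid_keywords: tuple[str, ...] = COVID_KEYWORDS

    def __post_init__(self) -> None:
        ids = [e.myth_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CatalogError(f"duplicate myth_ids: {sorted(dupes)}")
        if not self.covid_keywords:
            raise CatalogError("covid_keywords must be non-empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, myth_id: str) -> MythEntry:
        for e in self.entries:
            if e.myth_id == myth_id:
                return e
        raise KeyError(myth_id)

    @property
    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            counts[e.category] += 1
        return counts

    def queries(self) -> dict[str, QueryExpression]:
        """Build the search query for every entry, keyed by myth_id."""
        return {
            e.myth_id: build_query(e, list(self.covid_keywords)) for e in self.entries
        }


def load_catalog(path: str = "default") -> MythCatalog:
    """Load a myth catalog from CSV, or the packaged WHO Mythbuster table.

    The CSV needs columns ``myth_id``, ``keywords`` (semicolon-separated
    phrases), ``category``, and optionally ``mode`` (AND/OR, default AND)
    and reference ``n_tweets`` / ``n_users`` counts.
    """
    if path == "default":
        src = resources.files("mythcast.data").joinpath("who_myths.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"myth_id", "keywords", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog CSV missing columns: {sorted(missing)}")
    entries = []
    for idx, row in df.iterrows():
        kws = tuple(k.strip() for k in str(row["keywords"]).split(";") if k.strip())
        try:
            entries.append(
                MythEntry(
                    myth_id=str(row["myth_id"]),
                    keywords=kws,
                    category=str(row["category"]),
                    mode=str(row.get("mode", "AND")) if "mode" in df.columns else "AND",
                    n_tweets=int(row["n_tweets"]) if "n_tweets" in df.columns else None,
                    n_users=int(row["n_users"]) if "n_users" in df.columns else None,
                )
            )
        except CatalogError as err:
            raise CatalogError(f"row {idx}: {err}") from err
    return MythCatalog(entries=tuple(entries))


def build_query(
    entry: MythEntry, covid_keywords: Sequence[str]
) -> QueryExpression:
    """Build the boolean search query for one myth entry."""
    if not covid_keywords:
        raise CatalogError("covid_keywords must be non-empty")
    return QueryExpression(
        myth_terms=tuple(entry.keywords),
        covid_terms=tuple(covid_keywords),
        require_all=(entry.mode == "AND"),
    )


def match(text: str, query: QueryExpression, *, token_boundary: bool = False) -> bool:
    """True iff ``text`` satisfies ``query``.

    Containment is case-insensitive substring search on whitespace-normalised
    text; with ``token_boundary=True`` each phrase must additionally start and
    end at a non-alphanumeric boundary.
    """
    if not text:
        return False
    norm = _normalize(text)

    def contains(phrase: str) -> bool:
        p = _normalize(phrase)
        if not token_boundary:
            return p in norm
        return re.search(rf"(?<![0-9a-z]){re.escape(p)}(?![0-9a-z])", norm) is not None

    myth_hits = (contains(t) for t in query.myth_terms)
    myth_ok = all(myth_hits) if query.require_all else any(myth_hits)
    return myth_ok and any(contains(t) for t in query.covid_terms)


def summarize(
    catalog: MythCatalog,
    counts: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-category summary: number of myths, optionally tweet/user sums.

    ``counts`` maps myth_id -> (n_tweets, n_users); when omitted, the
    catalog's own reference counts are used if present. Tweet shares are
    fractions of the all-category tweet total.
    """
    if counts is not None:
        unknown = set(counts) - {e.myth_id for e in catalog.entries}
        if unknown:
            raise CatalogError(f"counts reference unknown myth_ids: {sorted(unknown)}")

    rows = []
    for cat in CATEGORIES:
        entries = [e for e in catalog.entries if e.category == cat]
        row: dict[str, object] = {"category": cat, "n_myths": len(entries)}
        if counts is not None:
            row["n_tweets"] = sum(counts.get(e.myth_id, (0, 0))[0] for e in entries)
            row["n_users"] = sum(counts.get(e.myth_id, (0, 0))[1] for e in entries)
        elif all(e.n_tweets is not None for e in catalog.entries):
            row["n_tweets"] = sum(e.n_tweets for e in entries)  # type: ignore[misc]
            row["n_users"] = sum(e.n_users or 0 for e in entries)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("category")
    if "n_tweets" in out.columns:
        total = int(out["n_tweets"].sum())
        if total > 0:
            out["tweet_share"] = out["n_tweets"] / total
    return out
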