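"""Tokenizing, Porter stemming and per-category top-term tables."""

import re
from pathlib import Path

import pytest

from mythcast import _porter
from mythcast.topics import (
    default_exclusions,
    porter_stem,
    term_tweet_proportions,
    tokenize,
    top_terms,
)

FIXTURE = Path(__file__).parent / "data" / "porter_pairs.tsv"


# --- independent re-implementation of the stemmer, used only as an oracle ---
# Written directly from the published rule tables in regex form; shares no
# code with mythcast._porter.

_C = "[^aeiou]"  # approximate; y handled by substitution below


def _enc(word):
    """Encode as consonant/vowel string with the y-after-consonant rule."""
    out = []
    for i, ch in enumerate(word):
        if ch in "aeiou":
            out.append("v")
        elif ch == "y":
            out.append("c" if i == 0 or out[i - 1] == "v" else "v")
        else:
            out.append("c")
    return "".join(out)


def _m(stem):
    return len(re.findall("v+c", _enc(stem)))


def _has_vowel(stem):
    return "v" in _enc(stem)


def _cvc(stem):
    return (
        len(stem) >= 3
        and _enc(stem)[-3:] == "cvc"
        and stem[-1] not in "wxy"
    )


def _dbl(stem):
    return len(stem) >= 2 and stem[-1] == stem[-2] and _enc(stem)[-1] == "c"


def _rule(word, rules, cond):
    for suf, rep in rules:
        if word.endswith(suf):
            stem = word[: len(word) - len(suf)]
            return stem + rep if cond(stem, suf) else word
    return word


def oracle_stem(word):
    w = word
    if len(w) <= 2:
        return w
    # step 1a
    for suf, rep in (("sses", "ss"), ("ies", "i"), ("ss", "ss"), ("s", "")):
        if w.endswith(suf):
            w = w[: len(w) - len(suf)] + rep
            break
    # step 1b
    if w.endswith("eed"):
        if _m(w[:-3]) > 0:
            w = w[:-1]
    else:
        hit = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            hit = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            hit = w[:-3]
        if hit is not None:
            w = hit
            if re.search("(at|bl|iz)$", w):
                w += "e"
            elif _dbl(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _m(w) == 1 and _cvc(w):
                w += "e"
    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"
    # steps 2 and 3 (m > 0)
    w = _rule(
        w,
        (
            ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
            ("anci", "ance"), ("izer", "ize"), ("abli", "able"), ("alli", "al"),
            ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
            ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
            ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
            ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
            ("biliti", "ble"),
        ),
        lambda stem, suf: _m(stem) > 0,
    )
    w = _rule(
        w,
        (
            ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
            ("ical", "ic"), ("ful", ""), ("ness", ""),
        ),
        lambda stem, suf: _m(stem) > 0,
    )
    # step 4 (m > 1; ion needs stem ending s or t)
    w = _rule(
        w,
        tuple(
            (s, "")
            for s in (
                "al", "ance", "ence", "er", "ic", "able", "ible", "ant",
                "ement", "ment", "ent", "ion", "ou", "ism", "ate", "iti",
                "ous", "ive", "ize",
            )
        ),
        lambda stem, suf: _m(stem) > 1
        and (suf != "ion" or (bool(stem) and stem[-1] in "st")),
    )
    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        if _m(stem) > 1 or (_m(stem) == 1 and not _cvc(stem)):
            w = stem
    # step 5b
    if _m(w) > 1 and _dbl(w) and w.endswith("l"):
        w = w[:-1]
    return w


def _fixture_pairs():
    steps = {
        "1a": _porter._step1a, "1b": _porter._step1b, "1c": _porter._step1c,
        "2": _porter._step2, "3": _porter._step3, "4": _porter._step4,
        "5": _porter._step5, "all": _porter.porter_stem,
    }
    for line in FIXTURE.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        step, word, expected = line.split("\t")
        yield steps[step], step, word, expected


class TestPorterStemmer:
    def test_published_reference_pairs_all_agree(self):
        """100% agreement with the published rule-example vocabulary."""
        failures = [
            (step, w, exp, fn(w))
            for fn, step, w, exp in _fixture_pairs()
            if fn(w) != exp
        ]
        assert failures == []

    def test_short_and_rule_free_tokens_unchanged(self):
        assert porter_stem("5g") == "5g"
        assert porter_stem("ox") == "ox"
        assert porter_stem("be") == "be"

    def test_agrees_with_independent_reimplementation(self):
        """Dual-route check over a programmatically generated vocabulary."""
        bases = """
            connect relate general oscillate motor trouble hope adjust
            depend activ spread detect prevent treat bleach mask breath
            vaccin network weather climate people virus drink inject
            caress pony tie feed agree plaster bleed sing conflate size
            hop tan fall hiss fizz fail file happy sky valid digit conform
            radical differ vile analog predic oper feudal decis callous
            formal sensit sensibl triplic elect good reviv allow infer
            airlin gyroscop defens irrit replac adopt homolog commun
            angular effect bowdler probat rat ceas control roll
        """.split()
        suffixes = (
            "", "s", "es", "ed", "ing", "er", "ation", "ations", "ness",
            "ful", "fulness", "al", "ally", "alli", "ization", "iviti",
            "ousli", "ement", "ent", "ance", "y", "ies", "ive", "ize",
        )
        vocab = sorted({b + s for b in bases for s in suffixes})
        assert len(vocab) > 1000
        mismatches = [w for w in vocab if porter_stem(w) != oracle_stem(w)]
        assert mismatches == []


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Injecting BLEACH?! http://x.co @who", ["injecting", "bleach"]),
            ("#5G towers", ["5g", "towers"]),
            ("", []),
            ("a I at", ["at"]),
            ("check www.example.com now", ["check", "now"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected


class TestTopTerms:
    def _recs(self, catalog, texts):
        import datetime as dt

        from mythcast.store import TweetRecord, UserProfile, label_tweets

        records = [
            TweetRecord(
                tweet_id=str(i),
                user=UserProfile(user_id=f"u{i}"),
                created_at=dt.datetime(2020, 3, 1, tzinfo=dt.timezone.utc),
                text=t,
            )
            for i, t in enumerate(texts)
        ]
        return label_tweets(records, catalog)

    def test_covid_stems_excluded_and_rank_one(self, catalog):
        labeled = self._recs(
            catalog,
            ["garlic covid19 helps", "garlic coronavirus helps", "garlic covid19"],
        )
        table = top_terms(labeled, "Prevent", k=3)
        assert table.terms[0][0] == "garlic"
        assert not {"covid19", "coronaviru", "covid"} & set(table.stems)

    def test_hand_counted_fixture_exact_table(self, catalog):
        texts = [
            "garlic covid19 miracle miracle cure",
            "garlic covid19 miracle cure cure",
            "garlic covid19 onion",
            "garlic covid19 onion cure",
            "garlic covid19 zebra",
            "garlic covid19 cure",
        ]
        labeled = self._recs(catalog, texts)
        table = top_terms(labeled, "Prevent", k=3, remove_stop_words=False)
        # garlic 6, cure 5, miracle 3, onion 2, zebra 1 (stems unchanged
        # except miracle -> miracl)
        assert table.terms == (("garlic", 6), ("cure", 5), ("miracl", 3))
        assert table.other_frequency == 3

    def test_tie_broken_lexicographically(self, catalog):
        labeled = self._recs(catalog, ["garlic covid19 zebra apple"])
        table = top_terms(labeled, "Prevent", k=2, remove_stop_words=False)
        assert [s for s, _ in table.terms] == ["appl", "garlic"]

    def test_empty_category_is_an_error(self, catalog):
        labeled = self._recs(catalog, ["garlic covid19"])
        with pytest.raises(ValueError, match="Treat"):
            top_terms(labeled, "Treat")

    def test_proportions_partition(self, catalog):
        texts = [
            "garlic covid19 cure",          # garlic (rank 1)
            "garlic covid19",               # garlic
            "alcohol cure covid19 zebra",   # cure via rank assignment
            "alcohol covid19 zebra",        # other (zebra not top)
        ]
        labeled = self._recs(catalog, texts)
        table = top_terms(labeled, "Prevent", k=2, remove_stop_words=False)
        props = dict(table.proportions)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
        ranked = table.stems
        # a tweet containing several top terms counts toward the highest rank
        multi = term_tweet_proportions(labeled, table, remove_stop_words=False)
        assert multi[ranked[0]] >= 0

    def test_overlapping_mode_reports_containment_fractions(self, catalog):
        labeled = self._recs(
            catalog, ["garlic covid19 cure", "garlic covid19", "alcohol covid19 cure"]
        )
        table = top_terms(labeled, "Prevent", k=2, remove_stop_words=False)
        any_props = term_tweet_proportions(
            labeled, table, remove_stop_words=False, assignment="any"
        )
        assert any_props["garlic"] == pytest.approx(2 / 3)

    def test_synthetic_corpus_top_terms_are_myth_words(self, labeled_small):
        table = top_terms(labeled_small, "Prevent", k=14)
        exclusions = default_exclusions()
        assert len(table.terms) == 14
        assert not exclusions & set(table.stems)
        freqs = [f for _, f in table.terms]
        assert freqs == sorted(freqs, reverse=True)
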