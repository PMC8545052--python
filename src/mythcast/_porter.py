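"""Porter suffix-stripping stemmer (the original 1980 algorithm).

A faithful implementation of Porter's rule-based stemmer: words are viewed
as ``[C](VC)^m[V]`` and suffixes are stripped in five steps, each rule
conditioned on the measure ``m`` of the remaining stem and on simple
letter predicates (*v* contains-a-vowel, *d double-consonant, *o ends
consonant-vowel-consonant with the final consonant not w, x or y). Only
words longer than two letters are altered.
"""

from __future__ import annotations

__all__ = ["porter_stem", "PorterStemmer"]

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """The m of [C](VC)^m[V]: the number of vowel→consonant transitions."""
    m = 0
    prev_cons = None
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if prev_cons is False and cons:
            m += 1
        prev_cons = cons
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace_suffix(word: str, suffix: str, replacement: str) -> str:
    return word[: len(word) - len(suffix)] + replacement


def _apply_rules(word: str, rules, min_measure: int) -> str | None:
    """First matching suffix wins; returns None when no rule matched."""
    for suffix, replacement in rules:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if _measure(stem) > min_measure:
                return stem + replacement
            return word
    return None


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return _replace_suffix(w, "sses", "ss")
    if w.endswith("ies"):
        return _replace_suffix(w, "ies", "i")
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    fired = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w, fired = w[:-2], True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w, fired = w[:-3], True
    if fired:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_consonant(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


def _step2(w: str) -> str:
    return _apply_rules(w, _STEP2, 0) or w


def _step3(w: str) -> str:
    return _apply_rules(w, _STEP3, 0) or w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    break
                w = stem
            break
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Stem one lowercase token with the original Porter algorithm."""
    w = word
    if len(w) <= 2:
        return w
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4, _step5):
        w = step(w)
    return w


class PorterStemmer:
    """Callable wrapper with a small memo cache."""

    def __init__(self) -> None:
        self._cache: dict[str, str] = {}

    def __call__(self, token: str) -> str:
        hit = self._cache.get(token)
        if hit is None:
            hit = self._cache[token] = porter_stem(token)
        return hit
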