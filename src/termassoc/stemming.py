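"""Porter suffix-stripping stemmer.

Implements the classical five-step Porter algorithm over lowercase ASCII
words. One deliberate deviation from the textbook rules: the bare ``S ->``
rule of step 1a does not fire on words ending in ``-us`` or ``-as``, so
Latin/Greek-style singulars common in biomedical text (*lupus*, *virus*,
*fungus*, *pancreas*, *atlas*) are left intact instead of losing their
final letter. The guard also makes the tokenise-stem pipeline stable on
its own output for such stems. Everything else follows the original rule
tables, applying the longest matching suffix within a step.
"""

from __future__ import annotations

from functools import lru_cache

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences: the m of [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(stem: str) -> bool:
    return (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and _is_consonant(stem, len(stem) - 1)
    )


def _ends_cvc(stem: str) -> bool:
    """*o condition: ends consonant-vowel-consonant, final not w, x or y."""
    if len(stem) < 3:
        return False
    return (
        _is_consonant(stem, len(stem) - 3)
        and not _is_consonant(stem, len(stem) - 2)
        and _is_consonant(stem, len(stem) - 1)
        and stem[-1] not in "wxy"
    )


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        if word.endswith(("us", "as")):  # Latin/Greek singular guard
            return word
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            return word[:-1]
        return word
    removed = None
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        removed = word[:-2]
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        removed = word[:-3]
    if removed is None:
        return word
    if removed.endswith(("at", "bl", "iz")):
        return removed + "e"
    if _ends_double_consonant(removed) and removed[-1] not in "lsz":
        return removed[:-1]
    if _measure(removed) == 1 and _ends_cvc(removed):
        return removed + "e"
    return removed


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


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


def _longest_rule(word: str, rules) -> tuple[str, str] | None:
    best = None
    for suffix, repl in rules:
        if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    return best


def _step2(word: str) -> str:
    hit = _longest_rule(word, _STEP2)
    if hit is not None:
        suffix, repl = hit
        stem = word[: len(word) - len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return word


def _step3(word: str) -> str:
    hit = _longest_rule(word, _STEP3)
    if hit is not None:
        suffix, repl = hit
        stem = word[: len(word) - len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return word


def _step4(word: str) -> str:
    best = None
    for suffix in _STEP4:
        if word.endswith(suffix) and (best is None or len(suffix) > len(best)):
            best = suffix
    if best is None:
        return word
    stem = word[: len(word) - len(best)]
    if _measure(stem) <= 1:
        return word
    if best == "ion" and not stem.endswith(("s", "t")):
        return word
    return stem


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if (
        word.endswith("l")
        and _ends_double_consonant(word)
        and _measure(word[:-1]) > 1
    ):
        return word[:-1]
    return word


@lru_cache(maxsize=65536)
def stem(token: str) -> str:
    """Stem a lowercase token; words of length <= 2 are returned unchanged."""
    word = token
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _step2(word)
    word = _step3(word)
    word = _step4(word)
    word = _step5a(word)
    word = _step5b(word)
    return word
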