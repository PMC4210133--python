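"""Porter's suffix-stripping stemmer for English.

Implements the original 1980 algorithm (steps 1a through 5b) without the
later "Porter2"/Snowball revisions: conflating rules operate on the measure
m of the stem, defined by viewing the word as [C](VC)^m[V] where C and V
are maximal consonant and vowel runs.  'y' counts as a consonant at the
start of a word or after a vowel, and as a vowel after a consonant.

Only lowercase ASCII words are meaningful inputs; words of length <= 2 are
returned unchanged, as the algorithm prescribes.
"""

from __future__ import annotations

__all__ = ["porter_stem"]


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in "aeiou":
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_consonant(stem, i)
        if prev_vowel and not vowel:
            m += 1
        prev_vowel = vowel
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
    # *o condition: stem ends consonant-vowel-consonant, final not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        return w[:-1] if _measure(w[:-3]) > 0 else w
    if w.endswith("ed"):
        stem = w[:-2]
        if not _contains_vowel(stem):
            return w
    elif w.endswith("ing"):
        stem = w[:-3]
        if not _contains_vowel(stem):
            return w
    else:
        return w
    # ed/ing removed: tidy up the exposed stem
    if stem.endswith(("at", "bl", "iz")):
        return stem + "e"
    if _ends_double_consonant(stem) and stem[-1] not in "lsz":
        return stem[:-1]
    if _measure(stem) == 1 and _ends_cvc(stem):
        return stem + "e"
    return stem


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _longest_rule(w: str, rules):
    """The rule with the longest matching suffix (matched, not applied)."""
    best = None
    for suffix, repl in rules:
        if w.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    return best


def _step2(w: str) -> str:
    rule = _longest_rule(w, _STEP2)
    if rule is not None:
        suffix, repl = rule
        stem = w[: -len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return w


def _step3(w: str) -> str:
    rule = _longest_rule(w, _STEP3)
    if rule is not None:
        suffix, repl = rule
        stem = w[: -len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return w


def _step4(w: str) -> str:
    rule = _longest_rule(w, [(s, "") for s in _STEP4])
    if rule is not None:
        suffix, _ = rule
        stem = w[: -len(suffix)]
        if _measure(stem) > 1:
            if suffix == "ion" and not stem.endswith(("s", "t")):
                return w
            return stem
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        return w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Stem a single lowercase word."""
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    w = _step2(w)
    w = _step3(w)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w
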