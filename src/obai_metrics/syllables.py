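"""Deterministic syllabification.

Readability formulas need syllable *counts*, not phonologically perfect
boundaries.  The algorithm is vowel-group counting with the usual English
orthographic corrections (silent final -e, syllabic -le, -ed only after
t/d, -es after sibilants), followed by a simple boundary-placement rule:

* no consonant between two vowel groups: split between the vowels;
* one consonant: the consonant starts the next syllable (V-CV);
* two or more: split after the first consonant (VC-CV).

It is total and deterministic over alphabetic strings: the same word always
yields the same syllables, independent of surrounding context.
"""

from __future__ import annotations

from .errors import NotAWord

_VOWELS = set("aeiouy")

#: words whose vowel-group count misleads; count corrections only
_EXCEPTIONS = {
    "people": ["peo", "ple"],
    "quiet": ["qui", "et"],
    "science": ["sci", "ence"],
    "being": ["be", "ing"],
    "idea": ["i", "de", "a"],
    "area": ["a", "re", "a"],
    "every": ["ev", "ery"],
}


def _vowel_positions(w: str) -> list[bool]:
    """Per-character flag: does this character act as a vowel?"""
    flags = []
    for i, ch in enumerate(w):
        if ch not in _VOWELS:
            flags.append(False)
        elif ch == "y":
            # y is a vowel unless word-initial or directly after a vowel
            flags.append(i > 0 and not flags[i - 1])
        elif ch == "u" and i > 0 and w[i - 1] == "q":
            flags.append(False)
        else:
            flags.append(True)
    return flags


def _vowel_groups(w: str) -> list[tuple[int, int]]:
    flags = _vowel_positions(w)
    groups: list[tuple[int, int]] = []
    i = 0
    n = len(w)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            groups.append((i, j))
            i = j
        else:
            i += 1
    return groups


def _drop_silent_final_e(w: str, groups: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if len(groups) < 2:
        return groups
    n = len(w)
    last = groups[-1]
    # final "-e": silent unless consonant + "le"
    if w.endswith("e") and last == (n - 1, n):
        if w.endswith("le") and n >= 3 and w[n - 3] not in _VOWELS:
            return groups
        return groups[:-1]
    # final "-ed": syllabic only after t or d
    if w.endswith("ed") and last == (n - 2, n - 1):
        if n >= 3 and w[n - 3] in "td":
            return groups
        return groups[:-1]
    # final "-es": syllabic only after a sibilant letter
    if w.endswith("es") and last == (n - 2, n - 1):
        if n >= 3 and w[n - 3] in "szx":
            return groups
        return groups[:-1]
    return groups


def syllabify(word: str, language: str = "en") -> list[str]:
    """Split ``word`` into syllable strings.

    Joining the returned syllables yields the lowercased word; the count is
    always at least one.  Raises :class:`NotAWord` for input without letters.
    """
    if word in _EXCEPTIONS:
        return list(_EXCEPTIONS[word])
    w = word.lower()
    if w in _EXCEPTIONS:
        return list(_EXCEPTIONS[w])
    if not any(ch.isalpha() for ch in w):
        raise NotAWord(f"not a word: {word!r}")
    groups = _drop_silent_final_e(w, _vowel_groups(w))
    if len(groups) <= 1:
        return [w]
    # boundary before each group after the first, adjusted for consonant runs
    boundaries = []
    for (s0, e0), (s1, e1) in zip(groups, groups[1:]):
        gap = s1 - e0
        if gap == 0:
            boundaries.append(s1)
        elif gap == 1:
            boundaries.append(e0)
        else:
            boundaries.append(e0 + 1)
    cuts = [0] + boundaries + [len(w)]
    return [w[a:b] for a, b in zip(cuts, cuts[1:])]


def syllable_count(word: str, language: str = "en") -> int:
    """Number of syllables in ``word``."""
    return len(syllabify(word, language))
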