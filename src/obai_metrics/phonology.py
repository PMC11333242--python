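"""Grapheme-to-phoneme conversion to IPA and the phonology measures.

G2P is a pluggable backend.  The bundled :class:`EnglishRuleG2P` combines a
pronunciation mini-lexicon with deterministic letter-to-sound rules; it is
context-sensitive at the lexical level — e.g. orthographic word-final "s"
surfaces as /z/ after a voiced segment ("is" -> /ɪz/, "dogs" -> /dɒɡz/) and
as /s/ after a voiceless one ("cats" -> /kæts/) — and applies silent-e and
magic-e handling so homophonic non-word spellings ("dake", "daik") map to
the same phoneme sequence.  An adapter for the external ``phonemizer``
package (espeak-ng) is provided for users who have it installed.

Phoneme sequences are lists of segment strings: affricates, diphthongs and
length-marked vowels are single segments, never split into code points.
Stress marks and ties are stripped for counting by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

from .errors import BackendError, EmptyInput, UnsupportedLanguage
from .text_core import AnnotatedDocument, RawText, annotate

_STRESS_AND_TIES = "ˈˌ͡‿."

#: pronunciation lexicon for frequent English words (segment lists)
_LEXICON: dict[str, list[str]] = {
    "the": ["ð", "ə"], "a": ["ə"], "an": ["æ", "n"],
    "is": ["ɪ", "z"], "was": ["w", "ɒ", "z"], "are": ["ɑː"], "were": ["w", "ɜː"],
    "be": ["b", "iː"], "been": ["b", "ɪ", "n"], "am": ["æ", "m"],
    "to": ["t", "ə"], "of": ["ɒ", "v"], "and": ["æ", "n", "d"], "or": ["ɔː"],
    "in": ["ɪ", "n"], "on": ["ɒ", "n"], "at": ["æ", "t"], "by": ["b", "aɪ"],
    "he": ["h", "iː"], "she": ["ʃ", "iː"], "it": ["ɪ", "t"], "we": ["w", "iː"],
    "i": ["aɪ"], "you": ["j", "uː"], "they": ["ð", "eɪ"], "my": ["m", "aɪ"],
    "this": ["ð", "ɪ", "s"], "that": ["ð", "æ", "t"], "there": ["ð", "ɛə"],
    "what": ["w", "ɒ", "t"], "who": ["h", "uː"], "with": ["w", "ɪ", "ð"],
    "one": ["w", "ʌ", "n"], "two": ["t", "uː"], "do": ["d", "uː"],
    "does": ["d", "ʌ", "z"], "have": ["h", "æ", "v"], "has": ["h", "æ", "z"],
    "said": ["s", "ɛ", "d"], "says": ["s", "ɛ", "z"], "word": ["w", "ɜː", "d"],
    "cat": ["k", "æ", "t"], "dog": ["d", "ɒ", "ɡ"], "house": ["h", "aʊ", "s"],
    "mat": ["m", "æ", "t"], "sat": ["s", "æ", "t"], "ball": ["b", "ɔː", "l"],
    "friend": ["f", "r", "ɛ", "n", "d"],
    "input": ["ɪ", "n", "p", "ʊ", "t"], "editor": ["ɛ", "d", "ɪ", "t", "ə"],
    "converted": ["k", "ə", "n", "v", "ɜː", "t", "ɪ", "d"],
    "always": ["ɔː", "l", "w", "eɪ", "z"], "water": ["w", "ɔː", "t", "ə"],
}

_DIGRAPHS: list[tuple[str, list[str]]] = [
    ("tch", ["tʃ"]), ("igh", ["aɪ"]),
    ("ch", ["tʃ"]), ("sh", ["ʃ"]), ("th", ["θ"]), ("ph", ["f"]), ("wh", ["w"]),
    ("ck", ["k"]), ("ng", ["ŋ"]), ("qu", ["k", "w"]),
    ("ee", ["iː"]), ("ea", ["iː"]), ("oo", ["uː"]), ("ou", ["aʊ"]),
    ("ow", ["aʊ"]), ("oa", ["əʊ"]), ("ai", ["eɪ"]), ("ay", ["eɪ"]),
    ("oi", ["ɔɪ"]), ("oy", ["ɔɪ"]), ("au", ["ɔː"]), ("aw", ["ɔː"]),
    ("ew", ["uː"]), ("ar", ["ɑː"]), ("or", ["ɔː"]), ("ir", ["ɜː"]),
    ("ur", ["ɜː"]), ("er", ["ə"]),
]

_MAGIC_E = {"a": "eɪ", "e": "iː", "i": "aɪ", "o": "əʊ", "u": "juː"}
_SHORT_VOWELS = {"a": "æ", "e": "ɛ", "i": "ɪ", "o": "ɒ", "u": "ʌ"}
_PLAIN_CONSONANTS = set("bdfhklmnprstvwz")

_VOWEL_CHARS = set("æɑɒɔəɛɜɪiʊuʌeaoɚᵻ")
_VOICED_CONSONANTS = {"b", "d", "ɡ", "g", "v", "ð", "z", "ʒ", "dʒ", "m", "n",
                      "ŋ", "l", "r", "w", "j"}
_SIBILANTS = {"s", "z", "ʃ", "ʒ", "tʃ", "dʒ"}


def _is_voiced(segment: str) -> bool:
    base = segment.strip(_STRESS_AND_TIES)
    return base in _VOICED_CONSONANTS or any(ch in _VOWEL_CHARS for ch in base)


@dataclass
class PhonemeSequence:
    segments: list[str]
    source_word: str
    language: str = "en"

    def stripped(self) -> list[str]:
        """Segments with stress marks and ties removed (for counting)."""
        out = []
        for s in self.segments:
            base = "".join(ch for ch in s if ch not in _STRESS_AND_TIES)
            if base:
                out.append(base)
        return out


@runtime_checkable
class G2PBackend(Protocol):
    def supports(self, language: str) -> bool: ...

    def convert(self, word: str) -> list[str]: ...


class EnglishRuleG2P:
    """Bundled deterministic English grapheme-to-phoneme backend."""

    language = "en"

    def supports(self, language: str) -> bool:
        return language == "en"

    def convert(self, word: str) -> list[str]:
        w = "".join(ch for ch in word.lower() if ch.isalpha())
        if not w:
            return []
        if w in _LEXICON:
            return list(_LEXICON[w])
        segments: list[str] = []
        n = len(w)
        # pre-compute silent-e positions
        silent = [False] * n
        if n >= 3 and w.endswith("e") and any(c in "aeiouy" for c in w[:-1]):
            silent[n - 1] = True
        ed_ending = w.endswith("ed") and n > 3
        es_ending = w.endswith("es") and n > 3
        i = 0
        while i < n:
            if silent[i]:
                i += 1
                continue
            # suffix handling
            if ed_ending and i == n - 2:
                prev = segments[-1] if segments else ""
                if prev.strip(_STRESS_AND_TIES) in ("t", "d"):
                    segments += ["ɪ", "d"]
                elif _is_voiced(prev):
                    segments.append("d")
                else:
                    segments.append("t")
                break
            if es_ending and i == n - 2:
                prev = segments[-1] if segments else ""
                if prev in _SIBILANTS:
                    segments += ["ɪ", "z"]
                elif _is_voiced(prev):
                    segments.append("z")
                else:
                    segments.append("s")
                break
            matched = False
            for graph, segs in _DIGRAPHS:
                if w.startswith(graph, i):
                    # vowel digraphs ending in r are handled whole; skip if the
                    # match would swallow a magic-e consonant slot
                    segments += segs
                    i += len(graph)
                    matched = True
                    break
            if matched:
                continue
            ch = w[i]
            # magic e: vowel + single consonant + silent final e
            if (
                ch in _MAGIC_E
                and i + 2 < n
                and w[i + 1] not in "aeiou"
                and w[i + 1] != "r"
                and (
                    (i + 2 == n - 1 and silent[n - 1])
                    or ((ed_ending or es_ending) and i + 2 == n - 2)
                )
            ):
                segments.append(_MAGIC_E[ch])
                i += 1
                continue
            if ch in _SHORT_VOWELS:
                segments.append(_SHORT_VOWELS[ch])
            elif ch == "y":
                if i == 0:
                    segments.append("j")
                elif i == n - 1:
                    segments.append("ɪ" if n > 2 else "aɪ")
                else:
                    segments.append("ɪ")
            elif ch == "c":
                segments.append("s" if i + 1 < n and w[i + 1] in "eiy" else "k")
            elif ch == "g":
                segments.append("dʒ" if i + 1 < n and w[i + 1] in "ey" else "ɡ")
            elif ch == "j":
                segments.append("dʒ")
            elif ch == "x":
                segments += ["k", "s"]
            elif ch == "s":
                # word-final s voices after a voiced segment
                if i == n - 1 and segments and not w.endswith("ss"):
                    segments.append("z" if _is_voiced(segments[-1]) else "s")
                else:
                    segments.append("s")
            elif ch in _PLAIN_CONSONANTS:
                segments.append("ɡ" if ch == "g" else ch)
            # duplicate letters collapse
            if i + 1 < n and w[i + 1] == ch and ch not in "aeiouy":
                i += 1
            i += 1
        return segments or ["ə"]


class PhonemizerG2P:  # pragma: no cover - optional external backend
    """Adapter for the external ``phonemizer`` package (espeak-ng)."""

    def __init__(self, language: str = "en-us"):
        try:
            from phonemizer.backend import EspeakBackend  # type: ignore
        except ImportError as exc:
            raise BackendError(
                "phonemizer is not installed (missing resource: package 'phonemizer')"
            ) from exc
        self._backend = EspeakBackend(language)
        self.language = language.split("-")[0]

    def supports(self, language: str) -> bool:
        return language == self.language

    def convert(self, word: str) -> list[str]:
        ipa = self._backend.phonemize([word], strip=True)[0].strip()
        # espeak output is a string; keep combining marks with their base
        import unicodedata

        segs: list[str] = []
        for ch in ipa:
            if segs and (unicodedata.combining(ch) or ch in "ːˑ"):
                segs[-1] += ch
            elif ch.strip():
                segs.append(ch)
        return segs


def get_g2p(language: str = "en", name: str = "rule") -> G2PBackend:
    if name == "rule":
        backend = EnglishRuleG2P()
        if not backend.supports(language):
            raise UnsupportedLanguage(
                f"the bundled G2P backend supports English only, got {language!r}"
            )
        return backend
    if name == "phonemizer":  # pragma: no cover
        return PhonemizerG2P("en-us" if language == "en" else language)
    raise BackendError(f"unknown G2P backend {name!r}")


def g2p(
    text: str | RawText | AnnotatedDocument,
    language: str = "en",
    backend: Optional[G2PBackend] = None,
) -> list[PhonemeSequence]:
    """Convert every word token of ``text`` to an IPA phoneme sequence."""
    if backend is None:
        backend = get_g2p(language)
    if isinstance(text, AnnotatedDocument):
        doc = text
    else:
        doc = annotate(text, language=language)
    out = []
    for t in doc.word_tokens():
        if not t.letter_count:
            continue
        segs = backend.convert(t.lower)
        out.append(PhonemeSequence(segments=segs, source_word=t.surface, language=doc.language))
    return out


@dataclass
class PhonologyReport:
    syllable_count: int
    syllable_word_ratio: float
    phoneme_counts: dict[str, int] = field(default_factory=dict)
    phoneme_proportions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "syllable_count": self.syllable_count,
            "syllable_word_ratio": self.syllable_word_ratio,
            "phoneme_counts": dict(self.phoneme_counts),
            "phoneme_proportions": dict(self.phoneme_proportions),
        }


def phonology_measures(
    doc: AnnotatedDocument, backend: Optional[G2PBackend] = None
) -> PhonologyReport:
    """Syllable counts, syllable/word ratio, and phoneme distributions."""
    words = doc.word_tokens()
    if not words:
        raise EmptyInput("document contains no words")
    syllables = sum(len(t.syllables) for t in words)
    counts: Counter[str] = Counter()
    for seq in g2p(doc, language=doc.language, backend=backend):
        counts.update(seq.stripped())
    total = sum(counts.values())
    proportions = {p: c / total for p, c in counts.items()} if total else {}
    return PhonologyReport(
        syllable_count=syllables,
        syllable_word_ratio=syllables / len(words),
        phoneme_counts=dict(counts),
        phoneme_proportions=proportions,
    )
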