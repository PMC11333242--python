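"""Synthetic test-text generator with exact ground truth.

Texts are built from a closed vocabulary whose syllabification is known, so
the generator can return the true word, sentence, syllable, passive-sentence
and difficult-word counts alongside the text — readability ground truth is
exact by construction, not re-derived through the pipeline under test.

Sentence templates are simple English SVO clauses:

* active:  ``The [adj ...] NOUN VERB the [adj ...] NOUN .``
* passive: ``The [adj ...] NOUN was PARTICIPLE by the [adj ...] NOUN .``

"Difficult" words are pronounceable nonce nouns absent from the bundled
easy-word list and dictionary.  The ``seed`` fixes the output exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidSpec
from .text_core import RawText

#: closed vocabulary with known syllable counts (validated against the
#: syllabifier in the test suite)
NOUNS = {
    1: ["cat", "dog", "sun", "boat", "fish", "bird", "king", "mat", "ball",
        "tree", "moon", "star", "hand", "road", "lake", "hill", "rock",
        "ship", "farm", "park", "street", "bed", "cup", "book", "chair",
        "clock", "door", "egg", "hat", "hen", "pig", "pond", "rope", "sand",
        "seat", "stone", "town", "wall", "wheel"],
    2: ["garden", "window", "paper", "basket", "bottle", "farmer", "kitchen",
        "letter", "market", "monkey", "mountain", "picture", "rabbit",
        "river", "sister", "teacher", "turtle", "winter", "butter", "corner",
        "dinner", "flower"],
    3: ["animal", "banana", "potato", "elephant", "holiday", "family",
        "yesterday", "afternoon"],
    4: ["watermelon", "caterpillar"],
}
ADJECTIVES = {
    1: ["red", "blue", "green", "old", "new", "big", "small", "warm", "cold",
        "soft", "tall", "wet", "dry", "fast", "slow"],
    2: ["yellow", "happy", "sunny", "silver", "golden", "purple", "simple",
        "gentle", "tidy", "fancy", "little", "pretty", "quiet", "busy"],
    3: ["wonderful", "beautiful"],
    4: ["watermelon", "caterpillar"],  # nouns reused attributively
}
ACTIVE_VERBS = ["saw", "found", "took", "made", "kept", "held"]
PARTICIPLES = ["seen", "found", "taken", "made", "kept", "held", "thrown"]

#: syllable counts for every vocabulary word (incl. function words)
WORD_SYLLABLES: dict[str, int] = {"the": 1, "was": 1, "by": 1}
for _pool in (NOUNS, ADJECTIVES):
    for _k, _words in _pool.items():
        for _w in _words:
            WORD_SYLLABLES[_w] = _k
for _w in ACTIVE_VERBS:
    WORD_SYLLABLES[_w] = 1
for _w, _k in [("seen", 1), ("found", 1), ("taken", 2), ("made", 1),
               ("kept", 1), ("held", 1), ("thrown", 1)]:
    WORD_SYLLABLES[_w] = _k

DIFFICULT_NONCE = {
    1: ["zorp", "blick", "fraz", "klim", "trop"],
    2: ["zorbal", "glimrod", "trandik", "plofnar", "vimlet"],
    3: ["zantoril", "morvanto", "fralindo", "bintoral"],
    4: ["zorbalino", "trandikolo", "morvantilo", "glimrodina"],
}
for _k, _words in DIFFICULT_NONCE.items():
    for _w in _words:
        WORD_SYLLABLES[_w] = _k

_UNIQUE_UNITS = ["zor", "bal", "tin", "mok", "vel", "rud", "pam", "fis", "lon", "dak"]


@dataclass
class FixtureSpec:
    n_sentences: int = 10
    words_per_sentence: int = 8
    syllable_profile: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    passive_fraction: float = 0.0
    difficult_word_fraction: float = 0.0
    vocabulary_size: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_sentences < 1:
            raise InvalidSpec("n_sentences must be >= 1")
        if self.words_per_sentence < 7:
            raise InvalidSpec("words_per_sentence must be >= 7 (template minimum)")
        for frac in (self.passive_fraction, self.difficult_word_fraction):
            if not 0.0 <= frac <= 1.0:
                raise InvalidSpec(f"fraction {frac} outside [0, 1]")
        if abs(sum(self.syllable_profile.values()) - 1.0) > 1e-9:
            raise InvalidSpec("syllable_profile must sum to 1")
        if any(k not in (1, 2, 3, 4) for k in self.syllable_profile):
            raise InvalidSpec("syllable_profile keys must be 1..4")


@dataclass
class FixtureTruth:
    """Exact ground truth for the generated text."""

    words: int
    sentences: int
    syllables: int
    passive_sentences: int
    difficult_words: int
    ttr: float
    word_tokens: list[str] = field(default_factory=list)


def _sample_syllables(rng: random.Random, profile: dict[int, float]) -> int:
    x = rng.random()
    acc = 0.0
    for k in sorted(profile):
        acc += profile[k]
        if x <= acc:
            return k
    return max(profile)


def generate_fixture(spec: FixtureSpec) -> tuple[RawText, FixtureTruth]:
    """Generate a fixture text and its exact ground-truth counts.

    Regenerating with the same spec (same seed) is byte-identical.  When
    ``vocabulary_size`` is at least the total word count, every emitted word
    is unique (ground-truth TTR 100); that mode requires
    ``passive_fraction == 0``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    total_words = spec.n_sentences * spec.words_per_sentence

    if spec.vocabulary_size is not None and spec.vocabulary_size >= total_words:
        if spec.passive_fraction > 0:
            raise InvalidSpec("all-unique mode cannot produce passive templates")
        return _generate_unique(spec, total_words)

    n_passive = round(spec.passive_fraction * spec.n_sentences)
    passive_idx = set(rng.sample(range(spec.n_sentences), n_passive))
    # content slots: adjectives + 2 nouns per sentence
    slots_per_sentence = [
        spec.words_per_sentence - (7 if s in passive_idx else 5)
        for s in range(spec.n_sentences)
    ]
    n_content = sum(a + 2 for a in slots_per_sentence)
    n_difficult = round(spec.difficult_word_fraction * total_words)
    if n_difficult > n_content:
        raise InvalidSpec(
            f"difficult_word_fraction needs {n_difficult} content slots, "
            f"only {n_content} available"
        )
    difficult_slots = set(rng.sample(range(n_content), n_difficult))

    def truncated(pool: list[str]) -> list[str]:
        if spec.vocabulary_size is None:
            return pool
        keep = max(1, round(spec.vocabulary_size * len(pool) / 120))
        return pool[:keep]

    slot_counter = 0
    sentences: list[str] = []
    tokens: list[str] = []
    syllables = 0

    def emit(word: str) -> str:
        nonlocal syllables
        tokens.append(word)
        syllables += WORD_SYLLABLES[word]
        return word

    def content_word(pool: dict[int, list[str]]) -> str:
        nonlocal slot_counter
        k = _sample_syllables(rng, spec.syllable_profile)
        if slot_counter in difficult_slots:
            word = rng.choice(DIFFICULT_NONCE[k])
        else:
            word = rng.choice(truncated(pool[k]))
        slot_counter += 1
        return word

    for s in range(spec.n_sentences):
        n_adj = slots_per_sentence[s]
        a = n_adj // 2
        b = n_adj - a
        parts = [emit("the").capitalize()]
        for _ in range(a):
            parts.append(emit(content_word(ADJECTIVES)))
        parts.append(emit(content_word(NOUNS)))
        if s in passive_idx:
            parts.append(emit("was"))
            parts.append(emit(rng.choice(PARTICIPLES)))
            parts.append(emit("by"))
        else:
            parts.append(emit(rng.choice(ACTIVE_VERBS)))
        parts.append(emit("the"))
        for _ in range(b):
            parts.append(emit(content_word(ADJECTIVES)))
        parts.append(emit(content_word(NOUNS)))
        sentences.append(" ".join(parts) + ".")

    text = " ".join(sentences)
    folded = [t.lower() for t in tokens]
    truth = FixtureTruth(
        words=len(tokens),
        sentences=spec.n_sentences,
        syllables=syllables,
        passive_sentences=n_passive,
        difficult_words=n_difficult,
        ttr=100.0 * len(set(folded)) / len(folded),
        word_tokens=folded,
    )
    return RawText(text, "en"), truth


def build_pid_document(
    n_propositions: int = 100, n_words: int = 1000, seed: int = 0
) -> RawText:
    """A text with a known proposition budget for idea-density benchmarks.

    Builds ``n_propositions / 2`` transitive clauses ("<noun> sees <noun>.")
    over unique nonce nouns — each clause contributes exactly one unique
    subject and one unique object proposition — padded to ``n_words`` word
    tokens with proposition-free interjection sentences.  The seed shuffles
    the noun assignment; the resulting counts are invariant to it.
    """
    if n_propositions % 2 or n_propositions < 2:
        raise InvalidSpec("n_propositions must be a positive even number")
    n_clauses = n_propositions // 2
    if n_words < 3 * n_clauses:
        raise InvalidSpec("n_words too small for the requested propositions")
    rng = random.Random(seed)
    nouns = []
    i = 0
    while len(nouns) < 2 * n_clauses:
        a, b, c = i % 10, (i // 10) % 10, (i // 100) % 10
        w = _UNIQUE_UNITS[a] + _UNIQUE_UNITS[b] + _UNIQUE_UNITS[c]
        # avoid suffixes the tagger reads as verbal/plural morphology
        if not w.endswith(("s", "ed", "ing", "ly")):
            nouns.append(w)
        i += 1
    rng.shuffle(nouns)
    sentences = []
    for k in range(n_clauses):
        subj, obj = nouns[2 * k], nouns[2 * k + 1]
        sentences.append(f"{subj.capitalize()} sees {obj}.")
    filler = n_words - 3 * n_clauses
    while filler > 0:
        take = min(filler, 10)
        sentences.append(" ".join(["Oh"] + ["oh"] * (take - 1)) + ".")
        filler -= take
    return RawText(" ".join(sentences), "en")


def _generate_unique(spec: FixtureSpec, total_words: int) -> tuple[RawText, FixtureTruth]:
    words = []
    for i in range(total_words):
        a, b, c = i % 10, (i // 10) % 10, (i // 100) % 10
        words.append(_UNIQUE_UNITS[a] + _UNIQUE_UNITS[b] + _UNIQUE_UNITS[c])
    assert len(set(words)) == total_words
    sentences = []
    for s in range(spec.n_sentences):
        chunk = words[s * spec.words_per_sentence:(s + 1) * spec.words_per_sentence]
        sentences.append(" ".join([chunk[0].capitalize()] + chunk[1:]) + ".")
    truth = FixtureTruth(
        words=total_words,
        sentences=spec.n_sentences,
        syllables=3 * total_words,
        passive_sentences=0,
        difficult_words=total_words,
        ttr=100.0,
        word_tokens=[w.lower() for w in words],
    )
    return RawText(" ".join(sentences), "en"), truth
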