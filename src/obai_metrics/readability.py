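"""The ten readability measures with their grade-level interpretations.

All formulas are computed exactly with their published coefficients:

* Flesch Reading Ease ``206.835 - 1.015 (W/S) - 84.6 (Syll/W)`` — the only
  capped score: values above 100 are reported as 100 (values below 0 as 0).
* Flesch-Kincaid grade ``0.39 (W/S) + 11.8 (Syll/W) - 15.59`` (unclamped).
* Gunning Fog ``0.4 [(W/S) + 100 (complex/W)]``, complex = 3+ syllables.
* Coleman-Liau ``0.0588 L - 0.296 S - 15.8`` with L, S per 100 words;
  the letter count uses letters only.
* Automated Readability Index ``4.71 (chars/W) + 0.5 (W/S)`` where the
  character count is letters+digits; ``conventional=True`` subtracts the
  widely used 21.43 constant instead.
* SMOG ``1.0430 sqrt(polysyllables * 30 / sentences) + 3.1291`` over three
  ten-sentence samples (beginning/middle/end) when the text has 30 or more
  sentences, otherwise over all sentences.
* Linsear Write: 1 point per word of <=2 syllables, 3 points per word of 3+,
  over the first 100 words; r = points/sentences; Lw = r/2 if r > 20 else
  r/2 - 1.
* Passive sentence percentage from passive dependency labels.
* Dale-Chall ``0.1579 (100 difficult/W) + 0.0496 (W/S)``; +3.6365 when the
  difficult-word share exceeds 5%.
* Difficult words: tokens (per occurrence, case-folded) outside the easy list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import EmptyInput, MissingResource, UnsupportedMeasure
from .text_core import AnnotatedDocument

PASSIVE_DEPS = {"nsubjpass", "auxpass", "nsubj:pass", "aux:pass"}
DALE_CHALL_ADJUSTMENT = 3.6365


@dataclass
class ReadabilityCounts:
    """Intermediate counts every formula draws on."""

    word_count: int
    sentence_count: int
    syllable_count: int
    letter_count: int
    character_count: int
    complex_word_count: int
    polysyllable_count: int
    difficult_word_count: Optional[int] = None
    passive_sentence_count: int = 0

    def validate(self) -> None:
        if self.word_count < 1 or self.sentence_count < 1:
            raise EmptyInput("readability needs at least one word and one sentence")


def counts_from_doc(
    doc: AnnotatedDocument, easy_words: Optional[frozenset[str]] = None
) -> ReadabilityCounts:
    """Derive :class:`ReadabilityCounts` from an annotated document.

    Clitic tokens are excluded from all word-based counts; punctuation never
    counts.  ``difficult_word_count`` is filled only when an easy-word list
    is given.
    """
    words = doc.word_tokens()
    if not words:
        raise EmptyInput("document contains no word tokens")
    syllables = sum(len(t.syllables) for t in words)
    complex_words = sum(1 for t in words if len(t.syllables) >= 3)
    difficult = None
    if easy_words is not None:
        difficult = sum(1 for t in words if t.lower not in easy_words)
    passive = sum(
        1
        for sent in doc.sentences()
        if any(t.dep_relation in PASSIVE_DEPS for t in sent)
    )
    return ReadabilityCounts(
        word_count=len(words),
        sentence_count=doc.n_sentences,
        syllable_count=syllables,
        letter_count=sum(t.letter_count for t in words),
        character_count=sum(sum(ch.isalnum() for ch in t.surface) for t in words),
        complex_word_count=complex_words,
        polysyllable_count=complex_words,
        difficult_word_count=difficult,
        passive_sentence_count=passive,
    )


# ---------------------------------------------------------------------------
# formulas on counts
# ---------------------------------------------------------------------------

def flesch_reading_ease(counts: ReadabilityCounts) -> tuple[float, float]:
    """Return ``(raw, reported)``; the reported score is capped to [0, 100]."""
    counts.validate()
    raw = (
        206.835
        - 1.015 * counts.word_count / counts.sentence_count
        - 84.6 * counts.syllable_count / counts.word_count
    )
    return raw, min(100.0, max(0.0, raw))


def flesch_kincaid_grade(counts: ReadabilityCounts) -> float:
    counts.validate()
    return (
        0.39 * counts.word_count / counts.sentence_count
        + 11.8 * counts.syllable_count / counts.word_count
        - 15.59
    )


def gunning_fog(counts: ReadabilityCounts) -> float:
    counts.validate()
    return 0.4 * (
        counts.word_count / counts.sentence_count
        + 100.0 * counts.complex_word_count / counts.word_count
    )


def coleman_liau(counts: ReadabilityCounts) -> float:
    counts.validate()
    letters_per_100 = counts.letter_count / counts.word_count * 100.0
    sentences_per_100 = counts.sentence_count / counts.word_count * 100.0
    return 0.0588 * letters_per_100 - 0.296 * sentences_per_100 - 15.8


def automated_readability_index(
    counts: ReadabilityCounts, conventional: bool = False
) -> float:
    counts.validate()
    score = (
        4.71 * counts.character_count / counts.word_count
        + 0.5 * counts.word_count / counts.sentence_count
    )
    return score - 21.43 if conventional else score


def smog(counts: ReadabilityCounts) -> float:
    counts.validate()
    return 1.0430 * math.sqrt(
        counts.polysyllable_count * 30.0 / counts.sentence_count
    ) + 3.1291


def smog_from_doc(doc: AnnotatedDocument) -> float:
    """SMOG with sampling: three ten-sentence samples (beginning, middle,
    end) when the document has >= 30 sentences, otherwise all sentences."""
    spans = doc.sentence_spans
    if not spans:
        raise EmptyInput("no sentences")
    if len(spans) >= 30:
        mid = len(spans) // 2 - 5
        chosen = spans[:10] + spans[mid:mid + 10] + spans[-10:]
    else:
        chosen = spans
    poly = 0
    for a, b in chosen:
        poly += sum(
            1 for t in doc.tokens[a:b] if t.counts_as_word and len(t.syllables) >= 3
        )
    return 1.0430 * math.sqrt(poly * 30.0 / len(chosen)) + 3.1291


def linsear_write(doc: AnnotatedDocument) -> float:
    """Linsear Write grade over the first 100-word sample.

    Shorter documents use all their words with points scaled to a 100-word
    basis.  The r <= 20 branch (Lw = r/2 - 1) applies inclusively at r = 20.
    """
    words = doc.word_tokens()
    if not words:
        raise EmptyInput("document contains no word tokens")
    sample = words[:100]
    points = sum(3 if len(t.syllables) >= 3 else 1 for t in sample)
    if len(sample) < 100:
        points *= 100.0 / len(sample)
    last_index = doc.tokens.index(sample[-1])
    n_sent = sum(1 for a, b in doc.sentence_spans if a <= last_index)
    r = points / max(n_sent, 1)
    return r / 2.0 if r > 20 else r / 2.0 - 1.0


def passive_percent(doc: AnnotatedDocument) -> float:
    """Percentage of sentences containing a passive construction."""
    if doc.n_sentences < 1:
        raise EmptyInput("no sentences")
    passive = sum(
        1
        for sent in doc.sentences()
        if any(t.dep_relation in PASSIVE_DEPS for t in sent)
    )
    return 100.0 * passive / doc.n_sentences


def dale_chall(
    counts: ReadabilityCounts, easy_words: Optional[frozenset[str]] = None
) -> tuple[float, float]:
    """Return ``(raw, adjusted)``; adjusted adds 3.6365 iff difficult > 5%."""
    counts.validate()
    if counts.difficult_word_count is None:
        raise MissingResource("Dale-Chall needs an easy-word list to count difficult words")
    fraction = counts.difficult_word_count / counts.word_count
    raw = 0.1579 * fraction * 100.0 + 0.0496 * counts.word_count / counts.sentence_count
    adjusted = raw + DALE_CHALL_ADJUSTMENT if fraction > 0.05 else raw
    return raw, adjusted


def difficult_words(doc: AnnotatedDocument, easy_words: frozenset[str]) -> int:
    """Count word tokens (case-folded, per occurrence) outside the easy list."""
    if easy_words is None or not easy_words:
        raise MissingResource("no easy-word list loaded")
    return sum(1 for t in doc.word_tokens() if t.lower not in easy_words)


# ---------------------------------------------------------------------------
# interpretation tables
# ---------------------------------------------------------------------------

_FLESCH_BANDS = [
    (90.0, "5th grade", "Very easy to read"),
    (80.0, "6th grade", "Easy to read"),
    (70.0, "7th grade", "Fairly easy to read"),
    (60.0, "8th and 9th grade", "Standard Plain English"),
    (50.0, "10th to 12th grade", "Fairly difficult to read"),
    (30.0, "College Level", "Difficult to read"),
    (10.0, "College Graduate", "Difficult for the general population"),
    (0.0, "Professional", "Exceptionally difficult to read"),
]

_COLEMAN_BANDS = [
    (17.0, "Professional", "Very hard"),
    (13.0, "College", "Difficult"),
    (11.0, "11th and 12th grade", "Relatively hard"),
    (8.0, "8th to 10th grade", "Conversational English"),
    (7.0, "7th grade", "Quite easy"),
    (6.0, "6th grade", "Easy to read"),
    (float("-inf"), "5th grade and below", "Very easy"),
]


def grade_label(measure: str, score: float) -> str:
    """Interpretation label for a score; boundary values take the upper band."""
    if measure in ("flesch_reading_ease", "flesch"):
        for low, grade, desc in _FLESCH_BANDS:
            if score >= low:
                return f"{grade} / {desc}"
        return f"{_FLESCH_BANDS[-1][1]} / {_FLESCH_BANDS[-1][2]}"
    if measure in ("coleman_liau", "coleman-liau"):
        for low, grade, desc in _COLEMAN_BANDS:
            if score >= low:
                return f"{grade} / {desc}"
    raise UnsupportedMeasure(f"no published level table for {measure!r}")


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class ReadabilityReport:
    counts: ReadabilityCounts
    flesch_reading_ease: float
    flesch_reading_ease_raw: float
    flesch_kincaid_grade: float
    gunning_fog: float
    coleman_liau: float
    automated_readability_index: float
    smog: float
    linsear_write: float
    passive_percent: float
    dale_chall_raw: Optional[float]
    dale_chall_adjusted: Optional[float]
    difficult_words: Optional[int]
    level_labels: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "flesch_reading_ease": self.flesch_reading_ease,
            "flesch_reading_ease_raw": self.flesch_reading_ease_raw,
            "flesch_kincaid_grade": self.flesch_kincaid_grade,
            "gunning_fog": self.gunning_fog,
            "coleman_liau": self.coleman_liau,
            "automated_readability_index": self.automated_readability_index,
            "smog": self.smog,
            "linsear_write": self.linsear_write,
            "passive_percent": self.passive_percent,
            "dale_chall_raw": self.dale_chall_raw,
            "dale_chall_adjusted": self.dale_chall_adjusted,
            "difficult_words": self.difficult_words,
        }
        return d


def readability_report(
    doc: AnnotatedDocument,
    easy_words: Optional[frozenset[str]] = None,
    ari_conventional: bool = False,
) -> ReadabilityReport:
    """Compute all ten readability measures for a document.

    Without an easy-word list the Dale-Chall scores and the difficult-word
    count are ``None``; pass :func:`obai_metrics.io_utils.load_easy_words`
    or a custom list to fill them.
    """
    counts = counts_from_doc(doc, easy_words)
    raw, capped = flesch_reading_ease(counts)
    cl = coleman_liau(counts)
    dc_raw = dc_adj = None
    if easy_words is not None:
        dc_raw, dc_adj = dale_chall(counts, easy_words)
    return ReadabilityReport(
        counts=counts,
        flesch_reading_ease=capped,
        flesch_reading_ease_raw=raw,
        flesch_kincaid_grade=flesch_kincaid_grade(counts),
        gunning_fog=gunning_fog(counts),
        coleman_liau=cl,
        automated_readability_index=automated_readability_index(counts, ari_conventional),
        smog=smog_from_doc(doc),
        linsear_write=linsear_write(doc),
        passive_percent=passive_percent(doc),
        dale_chall_raw=dc_raw,
        dale_chall_adjusted=dc_adj,
        difficult_words=counts.difficult_word_count,
        level_labels={
            "flesch_reading_ease": grade_label("flesch_reading_ease", capped),
            "coleman_liau": grade_label("coleman_liau", cl),
        },
    )
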