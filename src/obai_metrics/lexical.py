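"""Lexical measures: counts, function/content partition, propositional idea
density (PID), and the type-token-ratio family.

PID follows the dependency-based operationalization: a proposition is a
token whose dependency relation is in the proposition set (subjects, objects,
clausal modifiers/complements, relative clauses, and prepositional objects —
the last so that locative statements like "the cat was on the mat" count),
keyed by ``(relation, head lemma, dependent lemma)`` and deduplicated; PID is
the number of unique propositions divided by the number of word tokens.

Diversity measures operate on case-folded surface forms of word tokens
(``types="lemma"`` switches to lemmas):

* ``TTR  = 100 V / N``
* ``CTTR = V / sqrt(2N)``
* ``Maas = ln(ln V) / ln(ln N)`` (as printed; the canonical
  ``a^2 = (ln N - ln V)/ln^2 N`` is available with ``maas_canonical=True``)
* ``MSTTR``: mean per-segment TTR (as a 0-1 ratio) over complete segments
  of ``segment_size`` tokens (default 100); the incomplete tail is dropped
* ``Herdan's C = ln V / ln N``
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import EmptyInput, MissingAnnotation
from .text_core import AnnotatedDocument

FUNCTION_POS = {"ADP", "AUX", "CCONJ", "DET", "INTJ", "PART", "PRON", "SCONJ"}

PROPOSITION_DEPS = {
    "nsubj", "nsubjpass", "nsubj:pass", "csubj",
    "dobj", "obj", "iobj",
    "acl", "advcl", "relcl", "acl:relcl",
    "xcomp", "ccomp",
    "pobj", "obl",
}


@dataclass(frozen=True)
class Proposition:
    relation: str
    head_lemma: str
    dependent_lemma: str


@dataclass
class LexicalReport:
    characters: int
    character_density: float
    words: int
    sentences: int
    mean_sentence_length: float
    function_word_count: int
    function_word_proportion: float
    content_word_count: int
    content_word_proportion: float
    pid: float
    unique_propositions: int
    ttr: float
    cttr: float
    maas: Optional[float]
    msttr: Optional[float]
    herdan_c: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def basic_counts(doc: AnnotatedDocument) -> tuple[int, float, int, int, float]:
    """``(characters, character_density, words, sentences, mean_sentence_length)``.

    Characters are the non-whitespace characters of word tokens (punctuation
    excluded), so density reflects word length.
    """
    words = doc.word_tokens()
    if not words or doc.n_sentences < 1:
        raise EmptyInput("document contains no words")
    characters = sum(len(t.surface) for t in words)
    return (
        characters,
        characters / len(words),
        len(words),
        doc.n_sentences,
        len(words) / doc.n_sentences,
    )


def function_content_partition(
    doc: AnnotatedDocument,
) -> tuple[int, float, int, float]:
    """Counts and proportions of function vs content word tokens.

    Function words are adpositions, auxiliaries, coordinating conjunctions,
    determiners, interjections, particles, pronouns, and subordinating
    conjunctions; every other word token is a content word.
    """
    words = doc.word_tokens()
    if not words:
        raise EmptyInput("document contains no words")
    if any(not t.pos for t in words):
        raise MissingAnnotation("POS annotations are required")
    fn = sum(1 for t in words if t.pos in FUNCTION_POS)
    ct = len(words) - fn
    return fn, fn / len(words), ct, ct / len(words)


def extract_propositions(doc: AnnotatedDocument) -> set[Proposition]:
    """Unique propositions from the dependency parse (see module docstring)."""
    if any(not t.dep_relation for t in doc.word_tokens()):
        raise MissingAnnotation("dependency annotations are required")
    props = set()
    for t in doc.tokens:
        if t.dep_relation in PROPOSITION_DEPS and t.is_word:
            head = doc.tokens[t.head_index]
            props.add(Proposition(t.dep_relation, head.lemma, t.lemma))
    return props


def pid(doc: AnnotatedDocument) -> float:
    """Propositional idea density: unique propositions / word tokens."""
    words = doc.word_tokens()
    if not words:
        raise EmptyInput("document contains no words")
    return len(extract_propositions(doc)) / len(words)


def diversity(
    tokens: Sequence[str],
    segment_size: int = 100,
    maas_canonical: bool = False,
) -> tuple[float, float, Optional[float], Optional[float], Optional[float]]:
    """``(ttr, cttr, maas, msttr, herdan_c)`` over a token sequence.

    ``tokens`` should be case-folded word forms.  Logarithmic measures are
    ``None`` where undefined (Maas needs V and N above e; Herdan needs
    N >= 2).  MSTTR is ``None`` when no complete segment exists.
    """
    n = len(tokens)
    if n == 0:
        raise EmptyInput("no tokens")
    v = len(set(tokens))
    ttr = 100.0 * v / n
    cttr = v / math.sqrt(2.0 * n)
    maas: Optional[float] = None
    if maas_canonical:
        if n >= 2:
            maas = (math.log(n) - math.log(v)) / (math.log(n) ** 2)
    elif v > math.e and n > math.e:
        maas = math.log(math.log(v)) / math.log(math.log(n))
    herdan = math.log(v) / math.log(n) if n >= 2 else None
    segments = [
        tokens[i: i + segment_size]
        for i in range(0, n - segment_size + 1, segment_size)
    ]
    msttr = (
        sum(len(set(s)) / len(s) for s in segments) / len(segments)
        if segments
        else None
    )
    return ttr, cttr, maas, msttr, herdan


def lexical_report(
    doc: AnnotatedDocument,
    segment_size: int = 100,
    types: str = "surface",
    maas_canonical: bool = False,
) -> LexicalReport:
    """All lexical measures for a document in one report."""
    chars, density, words, sentences, msl = basic_counts(doc)
    fn, fnp, ct, ctp = function_content_partition(doc)
    props = extract_propositions(doc)
    tokens = [
        t.lemma if types == "lemma" else t.lower for t in doc.word_tokens()
    ]
    ttr, cttr, maas, msttr, herdan = diversity(
        tokens, segment_size=segment_size, maas_canonical=maas_canonical
    )
    return LexicalReport(
        characters=chars,
        character_density=density,
        words=words,
        sentences=sentences,
        mean_sentence_length=msl,
        function_word_count=fn,
        function_word_proportion=fnp,
        content_word_count=ct,
        content_word_proportion=ctp,
        pid=len(props) / words,
        unique_propositions=len(props),
        ttr=ttr,
        cttr=cttr,
        maas=maas,
        msttr=msttr,
        herdan_c=herdan,
    )
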