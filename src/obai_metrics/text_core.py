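"""Text normalization: tokens, sentences, and the pluggable annotation backend.

Every metric module consumes an :class:`AnnotatedDocument` produced here, so
tokenization conventions are fixed in one place:

* a *word token* contains at least one letter or digit; punctuation and
  symbols are separate non-word tokens and never enter word counts;
* possessive/contraction clitics (``'s``, ``n't``, ``'re``...) are split off
  as their own tokens (the possessive clitic is tagged as a particle) but are
  excluded from word, syllable, and letter counts;
* token indices are 0-based, sentence spans are half-open ``[start, stop)``
  intervals that partition the token list.

Annotation (lemma, POS, dependencies, entities) is delegated to a backend.
The default is the bundled deterministic rule-based English backend; an
adapter for spaCy's statistical pipelines is provided for users who have the
models installed.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterator, Optional, Protocol, runtime_checkable

from .errors import BackendError, EmptyInput, UnsupportedLanguage

#: languages the platform targets (ISO 639-1)
SUPPORTED_LANGUAGES = frozenset(
    ["en", "da", "nl", "fi", "fr", "de", "el", "it", "no", "pl", "pt", "ro", "ru", "es", "sv"]
)


@dataclass
class RawText:
    """A document to analyze: Unicode content plus its language code."""

    content: str
    language: str = "en"

    def validate(self) -> None:
        if not self.content or not self.content.strip():
            raise EmptyInput("document is empty or whitespace-only")
        if self.language not in SUPPORTED_LANGUAGES:
            raise UnsupportedLanguage(f"unsupported language code: {self.language!r}")


@dataclass
class Token:
    surface: str
    start: int = 0
    whitespace_after: str = ""
    lower: str = ""
    is_word: bool = False
    is_clitic: bool = False
    letter_count: int = 0
    syllables: list[str] = field(default_factory=list)
    lemma: str = ""
    pos: str = ""          # universal POS category (NOUN, VERB, AUX, ...)
    tag: str = ""          # fine-grained tag (Penn-style)
    pos_detail: str = ""   # human-readable description of `tag`
    dep_relation: str = ""
    head_index: int = -1
    entity_label: str = ""

    def __post_init__(self) -> None:
        if not self.lower:
            self.lower = self.surface.lower()
        self.is_word = any(ch.isalnum() for ch in self.surface)
        self.letter_count = sum(1 for ch in self.surface if ch.isalpha())

    @property
    def counts_as_word(self) -> bool:
        """Word token for counting purposes: alphanumeric and not a clitic."""
        return self.is_word and not self.is_clitic


@dataclass
class AnnotatedDocument:
    tokens: list[Token]
    sentence_spans: list[tuple[int, int]]
    language: str = "en"

    def sentences(self) -> Iterator[list[Token]]:
        for a, b in self.sentence_spans:
            yield self.tokens[a:b]

    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.counts_as_word]

    @property
    def n_sentences(self) -> int:
        return len(self.sentence_spans)

    def text(self) -> str:
        """Reconstruct the surface text (round-trips the original content)."""
        return "".join(t.surface + t.whitespace_after for t in self.tokens)


_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)+|\w+(?:['’]\w+)*|[^\w\s]")
_CLITIC_RE = re.compile(r"(?i)^(.+?)('s|’s|n't|n’t|'re|’re|'ll|’ll|'ve|’ve|'d|’d|'m|’m)$")
_TERMINALS = {".", "!", "?", "…"}
_CLOSERS = {'"', "'", "’", "”", ")", "]", "}"}


def tokenize(text: RawText | str, language: str = "en") -> list[Token]:
    """Break text into word and punctuation tokens, splitting clitics.

    Concatenating ``surface + whitespace_after`` over the result reconstructs
    the input (with CRLF newlines normalized to LF).
    """
    if isinstance(text, str):
        text = RawText(text, language)
    text.validate()
    content = unicodedata.normalize("NFC", text.content.replace("\r\n", "\n").replace("\r", "\n"))
    pieces: list[tuple[str, int]] = []
    for m in _TOKEN_RE.finditer(content):
        surf, pos = m.group(0), m.start()
        cl = _CLITIC_RE.match(surf)
        if cl and any(ch.isalpha() for ch in cl.group(1)):
            pieces.append((cl.group(1), pos))
            pieces.append((cl.group(2), pos + len(cl.group(1))))
        else:
            pieces.append((surf, pos))
    if not pieces:
        raise EmptyInput("document contains no tokens")
    tokens = []
    for i, (surf, pos) in enumerate(pieces):
        nxt = pieces[i + 1][1] if i + 1 < len(pieces) else len(content)
        tok = Token(surface=surf, start=pos, whitespace_after=content[pos + len(surf):nxt])
        tok.is_clitic = surf[0] in "'’" or tok.lower in {"n't", "n’t"}
        tokens.append(tok)
    return tokens


def segment_sentences(tokens: list[Token]) -> list[tuple[int, int]]:
    """Half-open sentence spans over the token list.

    A sentence ends at terminal punctuation (``. ! ? ...``), extended through
    any closing quotes or brackets; trailing unterminated material forms a
    final sentence.  At least one span is always returned.
    """
    if not tokens:
        raise EmptyInput("no tokens to segment")
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(tokens)
    while i < n:
        if not tokens[i].is_word and set(tokens[i].surface) <= _TERMINALS:
            j = i + 1
            while j < n and not tokens[j].is_word and tokens[j].surface in _CLOSERS:
                j += 1
            spans.append((start, j))
            start = j
            i = j
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    return spans


@runtime_checkable
class AnnotationBackend(Protocol):
    """Contract every annotation backend fulfils."""

    def supports(self, language: str) -> bool: ...

    def annotate(self, text: RawText) -> AnnotatedDocument: ...


class SpacyBackend:
    """Adapter around a spaCy pipeline for users with models installed.

    ``precision=True`` selects the larger, slightly more accurate model; the
    flag changes only the model, never any downstream formula.
    """

    _MODELS = {("en", False): "en_core_web_sm", ("en", True): "en_core_web_trf"}

    def __init__(self, language: str = "en", precision: bool = False, model: Optional[str] = None):
        try:
            import spacy  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise BackendError("spaCy is not installed (missing resource: package 'spacy')") from exc
        name = model or self._MODELS.get((language, precision))
        if name is None:  # pragma: no cover
            raise UnsupportedLanguage(f"no spaCy model configured for {language!r}")
        try:
            self._nlp = spacy.load(name)
        except OSError as exc:  # pragma: no cover
            raise BackendError(f"spaCy model unavailable (missing resource: {name!r})") from exc
        self.language = language

    def supports(self, language: str) -> bool:  # pragma: no cover - passthrough
        return language == self.language

    def annotate(self, text: RawText) -> AnnotatedDocument:  # pragma: no cover - needs models
        from .syllables import syllabify

        text.validate()
        doc = self._nlp(text.content)
        tokens: list[Token] = []
        spans: list[tuple[int, int]] = []
        for sent in doc.sents:
            a = len(tokens)
            for t in sent:
                if t.is_space:
                    continue
                tok = Token(surface=t.text, start=t.idx, whitespace_after=t.whitespace_)
                tok.is_clitic = t.text[0] in "'’" or t.text.lower() in {"n't"}
                tok.lemma = t.lemma_
                tok.pos = t.pos_
                tok.tag = t.tag_
                tok.pos_detail = t.tag_
                tok.dep_relation = t.dep_ if t.dep_ != "ROOT" else "ROOT"
                tok.head_index = t.head.i
                tok.entity_label = t.ent_type_
                if tok.counts_as_word and tok.letter_count:
                    tok.syllables = syllabify(t.text)
                tokens.append(tok)
            spans.append((a, len(tokens)))
        return AnnotatedDocument(tokens=tokens, sentence_spans=spans, language=text.language)


def get_backend(language: str = "en", precision: bool = False, name: str = "rule") -> AnnotationBackend:
    """Resolve an annotation backend by name (``rule`` or ``spacy``)."""
    if name == "rule":
        from ._rule_backend import RuleBasedEnglishBackend

        backend = RuleBasedEnglishBackend()
        if not backend.supports(language):
            raise UnsupportedLanguage(
                f"the bundled rule backend supports English only, got {language!r}"
            )
        return backend
    if name == "spacy":
        return SpacyBackend(language=language, precision=precision)
    raise BackendError(f"unknown backend {name!r}")


def annotate(
    text: RawText | str,
    language: str = "en",
    precision: bool = False,
    backend: Optional[AnnotationBackend] = None,
) -> AnnotatedDocument:
    """Produce a fully annotated document for the metric modules.

    Deterministic for a fixed backend and input.  ``precision`` selects a
    larger model where the backend offers one; it never alters any formula.
    """
    if isinstance(text, str):
        text = RawText(text, language)
    text.validate()
    if backend is None:
        backend = get_backend(text.language, precision)
    if not backend.supports(text.language):
        raise UnsupportedLanguage(f"backend does not support {text.language!r}")
    return backend.annotate(text)
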