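"""Batch document analysis: the full measure battery, one row per document.

Column names are ``<module>.<measure>`` in snake case and the column set is
identical across rows of a batch; measures that cannot be computed for a
document are explicitly null.  Per-file failures become error rows (the
``error`` column) without aborting the batch.  The schema version is
stamped in the returned metadata for longitudinal comparability.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import EmptyBatch, OBAIError
from .grammar_flags import detect_nonwords, detect_sentence_issues
from .io_utils import load_dictionary, load_easy_words, read_text
from .lexical import lexical_report
from .morphosyntax import UPOS_DISPLAY, constituent_counts, entity_distribution, pos_distribution
from .phonology import phonology_measures
from .readability import readability_report
from .text_core import AnnotatedDocument, AnnotationBackend, annotate

SCHEMA_VERSION = "1"

_ENTITY_LABELS = ["Person", "Place", "Organization", "Product", "Quantity"]
_POS_LABELS = [v for k, v in UPOS_DISPLAY.items() if k not in ("PUNCT", "SYM", "X")]

logger = logging.getLogger("obai_metrics.batch")


def _feature_columns() -> list[str]:
    cols = ["document_id", "error"]
    cols += [
        f"readability.{m}"
        for m in (
            "word_count", "sentence_count", "syllable_count",
            "flesch_reading_ease", "flesch_reading_ease_raw",
            "flesch_kincaid_grade", "gunning_fog", "coleman_liau",
            "automated_readability_index", "smog", "linsear_write",
            "passive_percent", "dale_chall_raw", "dale_chall_adjusted",
            "difficult_words",
        )
    ]
    cols += [
        f"lexical.{m}"
        for m in (
            "characters", "character_density", "words", "sentences",
            "mean_sentence_length", "function_word_count",
            "function_word_proportion", "content_word_count",
            "content_word_proportion", "pid", "unique_propositions",
            "ttr", "cttr", "maas", "msttr", "herdan_c",
        )
    ]
    cols += ["phonology.syllable_count", "phonology.syllable_word_ratio",
             "phonology.phoneme_types", "phonology.phoneme_tokens"]
    cols += [f"morphology.{lbl.lower().replace(' ', '_')}_count" for lbl in _POS_LABELS]
    cols += [f"morphology.{lbl.lower().replace(' ', '_')}_ratio" for lbl in _POS_LABELS]
    cols += ["syntax.sentences", "syntax.noun_phrases", "syntax.verb_phrases",
             "syntax.prepositional_phrases"]
    cols += [f"semantics.{lbl.lower()}_count" for lbl in _ENTITY_LABELS]
    cols += ["grammar.fragment_count", "grammar.run_on_count",
             "grammar.complex_sentence_count", "grammar.nonword_count",
             "grammar.hapax_nonword_count"]
    return cols


def document_features(
    doc: AnnotatedDocument,
    easy_words: Optional[frozenset[str]] = None,
    dictionary: Optional[frozenset[str]] = None,
) -> dict:
    """The full measure battery for one annotated document, flat-keyed."""
    easy_words = easy_words if easy_words is not None else load_easy_words()
    dictionary = dictionary if dictionary is not None else load_dictionary()
    row: dict = {}
    rr = readability_report(doc, easy_words=easy_words)
    row.update({
        "readability.word_count": rr.counts.word_count,
        "readability.sentence_count": rr.counts.sentence_count,
        "readability.syllable_count": rr.counts.syllable_count,
        **{f"readability.{k}": v for k, v in rr.to_dict().items()},
    })
    lex = lexical_report(doc)
    row.update({f"lexical.{k}": v for k, v in lex.to_dict().items()})
    ph = phonology_measures(doc)
    row["phonology.syllable_count"] = ph.syllable_count
    row["phonology.syllable_word_ratio"] = ph.syllable_word_ratio
    row["phonology.phoneme_types"] = len(ph.phoneme_counts)
    row["phonology.phoneme_tokens"] = sum(ph.phoneme_counts.values())
    pos = pos_distribution(doc)
    for lbl in _POS_LABELS:
        key = lbl.lower().replace(" ", "_")
        row[f"morphology.{key}_count"] = pos.counts.get(lbl, 0)
        row[f"morphology.{key}_ratio"] = pos.ratios.get(lbl, 0.0)
    syn = constituent_counts(doc)
    for k, v in syn.counts.items():
        row[f"syntax.{k}"] = v
    ents = entity_distribution(doc)
    for lbl in _ENTITY_LABELS:
        row[f"semantics.{lbl.lower()}_count"] = ents.counts.get(lbl, 0)
    sentence_flags = detect_sentence_issues(doc)
    nonword_flags = detect_nonwords(doc, dictionary)
    for kind in ("fragment", "run_on", "complex_sentence"):
        row[f"grammar.{kind}_count"] = sum(1 for f in sentence_flags if f.kind == kind)
    row["grammar.nonword_count"] = len(nonword_flags)
    row["grammar.hapax_nonword_count"] = sum(
        1 for f in nonword_flags if "hapax" in f.detail
    )
    return row


def analyze_batch(
    paths: Iterable[str | Path],
    language: str = "en",
    easy_words: Optional[frozenset[str]] = None,
    dictionary: Optional[frozenset[str]] = None,
    backend: Optional[AnnotationBackend] = None,
) -> tuple[pd.DataFrame, dict]:
    """Analyze text files and return ``(feature table, metadata)``.

    Row order matches input order; a file that cannot be read or analyzed
    yields an error row with null measures instead of aborting the batch.
    Raises :class:`EmptyBatch` when no path is given.
    """
    paths = list(paths)
    if not paths:
        raise EmptyBatch("no input files")
    columns = _feature_columns()
    rows = []
    for p in paths:
        p = Path(p)
        base = {c: None for c in columns}
        base["document_id"] = p.name
        base["error"] = ""
        try:
            doc = annotate(read_text(p), language=language, backend=backend)
            base.update(document_features(doc, easy_words, dictionary))
        except OBAIError as exc:
            base["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("skipping %s: %s", p, exc)
        rows.append(base)
    table = pd.DataFrame(rows, columns=columns)
    metadata = {"schema_version": SCHEMA_VERSION, "n_documents": len(rows),
                "language": language}
    table.attrs.update(metadata)
    return table, metadata
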