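"""POS distributions, dependency-derived constituent counts, named-entity
distributions, and the word-labeling table.

Constituents are read off the dependency parse (the annotation pipeline has
no constituency grammar): a noun phrase is a maximal nominal-headed subtree
(a nominal token not embedded in a larger nominal via a possessive or
compound link), a prepositional phrase is an adposition heading an object,
and a verb phrase is a non-auxiliary verbal head with its dependents.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import MissingAnnotation
from .text_core import AnnotatedDocument

UPOS_DISPLAY = {
    "NOUN": "Noun", "PROPN": "Proper noun", "VERB": "Verb", "AUX": "Auxiliary",
    "ADJ": "Adjective", "ADV": "Adverb", "PRON": "Pronoun", "PART": "Particle",
    "ADP": "Adposition", "DET": "Determiner", "CCONJ": "Coordinating conjunction",
    "SCONJ": "Subordinating conjunction", "INTJ": "Interjection", "NUM": "Numeral",
    "PUNCT": "Punctuation", "SYM": "Symbol", "X": "Other",
}

DEP_DISPLAY = {
    "ROOT": "Root", "nsubj": "Nominal Subject", "nsubjpass": "Nominal Subject (Passive)",
    "csubj": "Clausal Subject", "dobj": "Direct Object", "obj": "Direct Object",
    "iobj": "Indirect Object", "poss": "Possession Modifier", "case": "Case Marking",
    "det": "Determiner", "amod": "Adjectival Modifier", "advmod": "Adverbial Modifier",
    "aux": "Auxiliary", "auxpass": "Auxiliary (Passive)", "prep": "Prepositional Modifier",
    "pobj": "Object of Preposition", "attr": "Attribute", "compound": "Compound",
    "cc": "Coordinating Conjunction", "conj": "Conjunct", "mark": "Marker",
    "advcl": "Adverbial Clause Modifier", "ccomp": "Clausal Complement",
    "xcomp": "Open Clausal Complement", "relcl": "Relative Clause Modifier",
    "acl": "Clausal Modifier of Noun", "neg": "Negation Modifier",
    "intj": "Interjection", "parataxis": "Parataxis", "punct": "Punctuation",
    "dep": "Unclassified Dependent",
}


@dataclass
class DistributionReport:
    counts: dict[str, int] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "ratios": dict(self.ratios)}


def _require_annotations(doc: AnnotatedDocument, attr: str) -> None:
    if any(not getattr(t, attr) for t in doc.word_tokens()):
        raise MissingAnnotation(f"tokens lack {attr} annotations")


def pos_distribution(doc: AnnotatedDocument) -> DistributionReport:
    """Counts and ratios of universal POS categories over word tokens."""
    _require_annotations(doc, "pos")
    words = doc.word_tokens()
    counts = Counter(UPOS_DISPLAY.get(t.pos, t.pos) for t in words)
    total = len(words)
    return DistributionReport(
        counts=dict(counts),
        ratios={k: c / total for k, c in counts.items()},
    )


NOMINAL_POS = {"NOUN", "PROPN", "PRON"}
_NP_INTERNAL_DEPS = {"poss", "compound"}


def constituent_counts(doc: AnnotatedDocument) -> DistributionReport:
    """Sentence, noun-phrase, verb-phrase, and prepositional-phrase counts."""
    _require_annotations(doc, "dep_relation")
    has_pobj_child = set()
    for j, u in enumerate(doc.tokens):
        if u.dep_relation == "pobj" and u.head_index != j:
            has_pobj_child.add(u.head_index)
    nps = vps = pps = 0
    for i, t in enumerate(doc.tokens):
        if t.pos in NOMINAL_POS and t.tag != "PRP$":
            head = doc.tokens[t.head_index]
            embedded = t.dep_relation in _NP_INTERNAL_DEPS and head.pos in NOMINAL_POS
            if not embedded:
                nps += 1
        elif t.pos == "VERB":
            vps += 1
        elif t.pos == "ADP" and t.dep_relation == "prep" and i in has_pobj_child:
            pps += 1
    counts = {
        "sentences": doc.n_sentences,
        "noun_phrases": nps,
        "verb_phrases": vps,
        "prepositional_phrases": pps,
    }
    total = sum(counts.values())
    return DistributionReport(
        counts=counts,
        ratios={k: c / total for k, c in counts.items() if c} if total else {},
    )


def entity_distribution(doc: AnnotatedDocument) -> DistributionReport:
    """Counts per entity label over entity mentions.

    Adjacent tokens with the same label form one mention; repeated mentions
    count per occurrence.
    """
    mentions: list[str] = []
    prev_label = ""
    for t in doc.tokens:
        label = t.entity_label or ""
        if label and label != prev_label:
            mentions.append(label)
        elif label and label == prev_label and not mentions:
            mentions.append(label)
        prev_label = label if t.is_word else ""
    counts = Counter(mentions)
    total = sum(counts.values())
    return DistributionReport(
        counts=dict(counts),
        ratios={k: c / total for k, c in counts.items()} if total else {},
    )


@dataclass
class WordLabelRow:
    word: str
    syllables: list[str]
    lemma: str
    pos: str
    pos_detail: str
    dependency: str


def word_label_table(doc: AnnotatedDocument) -> list[WordLabelRow]:
    """One row per word token in document order (punctuation excluded)."""
    _require_annotations(doc, "pos")
    rows = []
    for t in doc.tokens:
        if not t.is_word:
            continue
        rows.append(
            WordLabelRow(
                word=t.surface,
                syllables=list(t.syllables),
                lemma=t.lemma,
                pos=UPOS_DISPLAY.get(t.pos, t.pos),
                pos_detail=t.pos_detail,
                dependency=DEP_DISPLAY.get(t.dep_relation, t.dep_relation),
            )
        )
    return rows


def word_label_dataframe(doc: AnnotatedDocument) -> pd.DataFrame:
    """The word-labeling table as a DataFrame with its canonical columns."""
    rows = word_label_table(doc)
    return pd.DataFrame(
        {
            "Word": [r.word for r in rows],
            "Syllables": [
                ", ".join(f"'{s}'" for s in r.syllables) if r.syllables else "None"
                for r in rows
            ],
            "Lemma": [r.lemma for r in rows],
            "POS": [r.pos for r in rows],
            "POS Details": [r.pos_detail for r in rows],
            "Dependencies": [r.dependency for r in rows],
        }
    )
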