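"""Heuristic grammar-error flags: fragments, run-ons, complex sentences,
and dictionary-based nonword (neologism / phonemic-paraphasia) candidates.

A *fragment* is a sentence with no finite verb carrying a subject (its root
is not a finite predicate).  A *run-on* contains two or more independent
finite clauses joined without a coordinating conjunction or separating
punctuation; a clause introduced by a subordinating conjunction or relative
word does not count as independent.  A *complex sentence* carries at least
``complex_clause_threshold`` subordinate clauses (default 3 — the threshold
is a tunable heuristic, not a normative definition).

Nonword flags compare each word token to a dictionary; a nonword that also
occurs exactly once in the document is additionally marked as a hapax
legomenon.  Nonwords within edit distance ``paraphasia_distance`` (default
2) of some dictionary word are labelled phonemic-paraphasia candidates,
the rest neologism candidates.  Tokens recognized as named entities are
skipped (proper names are not neologisms).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .clinical_scoring import osa_distance
from .errors import MissingAnnotation, MissingResource
from .text_core import AnnotatedDocument

FINITE_TAGS = {"VBD", "VBZ", "VBP", "MD"}
SUBORDINATE_DEPS = {"advcl", "ccomp", "xcomp", "relcl", "acl"}
SUBORDINATOR_TAGS = {"WDT", "WP", "WRB"}


@dataclass
class GrammarFlag:
    kind: str  # fragment | run_on | complex_sentence | nonword
    sentence_index: Optional[int] = None
    token_index: Optional[int] = None
    detail: str = ""


def _independent_clauses(doc: AnnotatedDocument, lo: int, hi: int) -> list[tuple[int, int, bool]]:
    """(subject_index, verb_index, separated) triples for finite clauses.

    ``separated`` records whether a coordinating conjunction or punctuation
    occurs between this clause and the previous one.  Subordinate clauses
    (introduced by a subordinating conjunction or wh-word) are excluded.
    """
    toks = doc.tokens
    clauses = []
    last_end = lo
    i = lo
    while i < hi:
        t = toks[i]
        if t.tag in FINITE_TAGS and t.pos in ("VERB", "AUX"):
            # find this verb's subject: nearest preceding nominal not yet used
            subj = None
            subordinate = False
            for j in range(i - 1, last_end - 1, -1):
                u = toks[j]
                if u.pos == "SCONJ" or u.tag in SUBORDINATOR_TAGS:
                    subordinate = True
                if subj is None and u.pos in ("NOUN", "PROPN", "PRON") and u.tag != "PRP$":
                    subj = j
            # an auxiliary followed by its main verb is one predicate
            if t.pos == "AUX" and any(
                toks[k].pos == "VERB" for k in range(i + 1, min(i + 3, hi))
            ):
                i += 1
                continue
            if subj is not None and not subordinate:
                separated = any(
                    toks[k].pos == "CCONJ" or not toks[k].is_word
                    for k in range(last_end, subj)
                )
                clauses.append((subj, i, separated))
                last_end = i + 1
        i += 1
    return clauses


def detect_sentence_issues(
    doc: AnnotatedDocument, complex_clause_threshold: int = 3
) -> list[GrammarFlag]:
    """Fragment, run-on, and complex-sentence flags per sentence."""
    if any(not t.dep_relation for t in doc.word_tokens()):
        raise MissingAnnotation("dependency annotations are required")
    flags: list[GrammarFlag] = []
    for s, (lo, hi) in enumerate(doc.sentence_spans):
        toks = doc.tokens[lo:hi]
        if not any(t.is_word for t in toks):
            continue
        finite = [
            t for t in toks if t.tag in FINITE_TAGS and t.pos in ("VERB", "AUX")
        ]
        has_participle_pred = any(
            t.tag == "VBN" and t.dep_relation in ("ROOT", "conj", "parataxis")
            for t in toks
        )
        has_subject = any(
            t.dep_relation in ("nsubj", "nsubjpass", "csubj") for t in toks
        )
        if not ((finite or has_participle_pred) and has_subject):
            flags.append(
                GrammarFlag("fragment", sentence_index=s,
                            detail="no finite predicate with a subject")
            )
            continue
        clauses = _independent_clauses(doc, lo, hi)
        unseparated = sum(1 for (_, _, sep) in clauses[1:] if not sep)
        if len(clauses) >= 2 and unseparated >= 1:
            flags.append(
                GrammarFlag(
                    "run_on", sentence_index=s,
                    detail=f"{len(clauses)} independent clauses without "
                           "conjunction or punctuation",
                )
            )
        n_sub = sum(1 for t in toks if t.dep_relation in SUBORDINATE_DEPS)
        if n_sub >= complex_clause_threshold:
            flags.append(
                GrammarFlag("complex_sentence", sentence_index=s,
                            detail=f"{n_sub} subordinate clauses")
            )
    return flags


def detect_nonwords(
    doc: AnnotatedDocument,
    dictionary: Optional[frozenset[str]] = None,
    paraphasia_distance: int = 2,
) -> list[GrammarFlag]:
    """Flag word tokens absent from the dictionary.

    Each flag's detail distinguishes phonemic-paraphasia candidates (close
    to a dictionary word) from neologism candidates, and marks hapax
    legomena (document frequency 1).
    """
    if dictionary is None:
        from .io_utils import load_dictionary

        dictionary = load_dictionary()
    if not dictionary:
        raise MissingResource("empty dictionary")
    freq = Counter(t.lower for t in doc.word_tokens())
    flags = []
    for i, t in enumerate(doc.tokens):
        if not t.counts_as_word or not t.letter_count:
            continue
        if t.entity_label or t.pos == "PROPN":
            continue
        w = t.lower
        if w in dictionary or (t.lemma and t.lemma in dictionary):
            continue
        near = any(
            abs(len(w) - len(d)) <= paraphasia_distance
            and osa_distance(w, d) <= paraphasia_distance
            for d in dictionary
        )
        kind_detail = "phonemic paraphasia candidate" if near else "neologism candidate"
        if freq[w] == 1:
            kind_detail += "; hapax legomenon"
        flags.append(GrammarFlag("nonword", token_index=i, detail=kind_detail))
    return flags
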