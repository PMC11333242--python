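"""Deterministic rule-based English annotation backend.

A small closed-class lexicon plus suffix heuristics for tagging, a
rule-based lemmatizer validated against the bundled dictionary, and a
pattern-driven dependency attacher.  It is not a statistical parser: its
purpose is to provide reproducible lemma/POS/dependency/entity labels for
the constructions the measures rely on (possessives, passives,
subject/object relations, prepositional phrases, subordinate markers)
without downloading any model.  Output is a pure function of the input.
"""

from __future__ import annotations

from .syllables import syllabify
from .text_core import AnnotatedDocument, AnnotationBackend, RawText, Token, segment_sentences, tokenize

# ---------------------------------------------------------------------------
# lexical tables
# ---------------------------------------------------------------------------

DETERMINERS = {
    "the", "a", "an", "this", "that", "these", "those", "both", "each",
    "every", "all", "some", "any", "no", "another", "either", "neither",
}
PRON_PERS = {
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us",
    "them", "mine", "yours", "hers", "ours", "theirs", "myself", "yourself",
    "himself", "herself", "itself", "ourselves", "themselves", "someone",
    "anyone", "everyone", "nobody", "something", "anything", "everything",
}
PRON_POSS = {"my", "your", "his", "its", "our", "their"}  # "her" resolved in context
WH_PRON = {"who", "whom", "what"}
WH_DET = {"which", "whose"}
WH_ADV = {"where", "why", "how"}  # "when" resolved as SCONJ below
PREPOSITIONS = {
    "in", "on", "at", "by", "for", "with", "from", "of", "about", "into",
    "onto", "under", "over", "between", "through", "during", "against",
    "without", "within", "near", "behind", "beyond", "across", "along",
    "around", "toward", "towards", "upon", "off", "up", "down", "out",
    "inside", "outside", "above", "below", "past",
}
SCONJS = {
    "because", "if", "although", "though", "unless", "while", "whereas",
    "since", "until", "whenever", "when", "after", "before", "as", "once",
}
CCONJS = {"and", "or", "but", "nor", "yet", "so"}
INTERJECTIONS = {"oh", "ah", "yes", "wow", "hey", "hello", "hi", "ouch",
                 "oops", "yeah", "hmm", "huh", "uh", "um", "well"}
MODALS = {"will", "would", "can", "could", "shall", "should", "may", "might", "must"}
BE_FORMS = {"be": "VB", "am": "VBP", "is": "VBZ", "are": "VBP", "was": "VBD",
            "were": "VBD", "been": "VBN", "being": "VBG"}
HAVE_FORMS = {"have": "VBP", "has": "VBZ", "had": "VBD", "having": "VBG"}
DO_FORMS = {"do": "VBP", "does": "VBZ", "did": "VBD", "done": "VBN", "doing": "VBG"}
AUX_WORDS = set(BE_FORMS) | set(HAVE_FORMS) | set(DO_FORMS) | MODALS

ADVERBS = {
    "always", "never", "often", "sometimes", "very", "too", "not", "also",
    "here", "there", "now", "then", "today", "yesterday", "tomorrow", "soon",
    "again", "away", "back", "still", "just", "already", "almost", "quite",
    "rather", "maybe", "perhaps", "together", "twice", "once",
}

#: irregular verb form -> (lemma, penn tag); VBN forms double as VBD where ambiguous
IRREGULAR_VERBS = {
    "sat": ("sit", "VBD"), "ran": ("run", "VBD"), "fell": ("fall", "VBD"),
    "saw": ("see", "VBD"), "seen": ("see", "VBN"), "sees": ("see", "VBZ"),
    "threw": ("throw", "VBD"), "thrown": ("throw", "VBN"),
    "took": ("take", "VBD"), "taken": ("take", "VBN"), "takes": ("take", "VBZ"),
    "made": ("make", "VBD"), "kept": ("keep", "VBD"), "held": ("hold", "VBD"),
    "found": ("find", "VBD"), "gave": ("give", "VBD"), "given": ("give", "VBN"),
    "went": ("go", "VBD"), "gone": ("go", "VBN"), "goes": ("go", "VBZ"),
    "came": ("come", "VBD"), "said": ("say", "VBD"), "told": ("tell", "VBD"),
    "wrote": ("write", "VBD"), "written": ("write", "VBN"),
    "ate": ("eat", "VBD"), "eaten": ("eat", "VBN"), "got": ("get", "VBD"),
    "slept": ("sleep", "VBD"), "felt": ("feel", "VBD"), "left": ("leave", "VBD"),
    "built": ("build", "VBD"), "bought": ("buy", "VBD"), "brought": ("bring", "VBD"),
    "broke": ("break", "VBD"), "broken": ("break", "VBN"), "knew": ("know", "VBD"),
    "known": ("know", "VBN"), "grew": ("grow", "VBD"), "grown": ("grow", "VBN"),
    "spoke": ("speak", "VBD"), "spoken": ("speak", "VBN"), "sang": ("sing", "VBD"),
    "drove": ("drive", "VBD"), "driven": ("drive", "VBN"), "lost": ("lose", "VBD"),
    "met": ("meet", "VBD"), "put": ("put", "VBD"), "read": ("read", "VBD"),
    "sent": ("send", "VBD"), "heard": ("hear", "VBD"), "caught": ("catch", "VBD"),
}
IRREGULAR_NOUNS = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose",
}

#: base-form verbs the tagger may meet untagged (present plural/base)
BASE_VERBS = {
    "run", "sit", "see", "throw", "take", "make", "keep", "hold", "find",
    "give", "go", "come", "say", "tell", "write", "eat", "get", "sleep",
    "feel", "leave", "build", "buy", "bring", "break", "know", "grow",
    "speak", "sing", "drive", "lose", "meet", "put", "read", "send", "hear",
    "catch", "walk", "talk", "play", "jump", "help", "look", "want", "need",
    "like", "love", "live", "work", "call", "ask", "use", "sleep", "purr",
    "bark", "swim", "fly", "cook", "paint", "clean", "open", "close",
}

GAZETTEER = {
    "napoleon": "Person", "john": "Person", "mary": "Person", "anna": "Person",
    "peter": "Person", "sarah": "Person", "james": "Person", "emma": "Person",
    "iris": "Person", "agatha": "Person", "ronald": "Person",
    "france": "Place", "paris": "Place", "london": "Place", "oslo": "Place",
    "norway": "Place", "rome": "Place", "spain": "Place", "europe": "Place",
    "america": "Place", "england": "Place", "athens": "Place",
    "unicef": "Organization", "google": "Organization", "nato": "Organization",
    "microsoft": "Organization",
}

PENN_DESCRIPTIONS = {
    "NN": "Noun, Singular or Mass", "NNS": "Noun, Plural",
    "NNP": "Proper Noun, Singular", "NNPS": "Proper Noun, Plural",
    "VB": "Verb, Base Form", "VBD": "Verb, Past Tense",
    "VBG": "Verb, Gerund or Present Participle", "VBN": "Verb, Past Participle",
    "VBP": "Verb, Non-3Rd Person Singular Present",
    "VBZ": "Verb, 3Rd Person Singular Present", "MD": "Modal",
    "JJ": "Adjective", "JJR": "Adjective, Comparative", "JJS": "Adjective, Superlative",
    "RB": "Adverb", "RBR": "Adverb, Comparative", "RBS": "Adverb, Superlative",
    "PRP": "Pronoun, Personal", "PRP$": "Pronoun, Possessive",
    "DT": "Determiner", "WDT": "Wh-Determiner", "WP": "Wh-Pronoun", "WRB": "Wh-Adverb",
    "IN": "Preposition or Subordinating Conjunction", "CC": "Coordinating Conjunction",
    "POS": "Possessive Ending", "TO": "To", "UH": "Interjection",
    "CD": "Cardinal Number", "EX": "Existential There", "RP": "Particle",
    "PUNCT": "Punctuation", "SYM": "Symbol", "FW": "Foreign Word",
}


def penn_to_upos(tag: str, lower: str) -> str:
    if lower in AUX_WORDS and tag.startswith("VB") or tag == "MD":
        return "AUX"
    if tag.startswith("NNP"):
        return "PROPN"
    if tag.startswith("NN"):
        return "NOUN"
    if tag.startswith("VB"):
        return "VERB"
    if tag.startswith("JJ"):
        return "ADJ"
    if tag.startswith("RB") or tag == "WRB":
        return "PART" if lower == "not" else "ADV"
    if tag in ("PRP", "PRP$", "WP"):
        return "PRON"
    if tag in ("DT", "WDT", "EX"):
        return "DET"
    if tag == "IN":
        return "SCONJ" if lower in SCONJS else "ADP"
    if tag == "CC":
        return "CCONJ"
    if tag in ("POS", "TO", "RP"):
        return "PART"
    if tag == "UH":
        return "INTJ"
    if tag == "CD":
        return "NUM"
    if tag == "PUNCT":
        return "PUNCT"
    if tag == "SYM":
        return "SYM"
    return "X"


# ---------------------------------------------------------------------------
# tagging
# ---------------------------------------------------------------------------

#: nouns that look adverbial/verbal to the suffix rules
NOUN_EXCEPTIONS = {"family", "butterfly", "jelly", "belly", "lily", "pony",
                   "daisy", "ceiling", "morning", "evening", "building",
                   "thing", "something", "nothing", "spring", "ring", "king"}

_NOMINAL_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ship", "dom", "ism", "ance", "ence")
_ADJ_SUFFIXES = ("ful", "ous", "ive", "ible", "able", "ish", "less", "ic", "ary")


def _dictionary() -> set[str]:
    from .io_utils import load_dictionary

    return load_dictionary()


class RuleBasedEnglishBackend:
    """The bundled deterministic annotation backend (English)."""

    language = "en"

    def __init__(self) -> None:
        self._dict = _dictionary()

    def supports(self, language: str) -> bool:
        return language == "en"

    # -- tagging ------------------------------------------------------------

    def _tag_sentence(self, toks: list[Token], lo: int, hi: int) -> None:
        first_word = next((i for i in range(lo, hi) if toks[i].is_word), lo)
        for i in range(lo, hi):
            t = toks[i]
            prev = toks[i - 1] if i > lo else None
            t.tag = self._tag_one(t, prev, sent_initial=(i == first_word))
        # contextual repairs
        for i in range(lo, hi):
            t = toks[i]
            prev = toks[i - 1] if i > lo else None
            nxt = toks[i + 1] if i + 1 < hi else None
            # participle between determiner and noun is adjectival
            if t.tag in ("VBD", "VBN") and prev is not None and prev.tag in ("DT", "PRP$", "JJ"):
                if nxt is not None and nxt.tag.startswith("NN"):
                    t.tag = "JJ"
            # "her" before a nominal is possessive
            if t.lower == "her" and nxt is not None and (
                nxt.tag.startswith("NN") or nxt.tag == "JJ"
            ):
                t.tag = "PRP$"
            # past participle after a form of be/have, skipping adverbs
            if t.tag == "VBD":
                j = i - 1
                while j >= lo and toks[j].tag in ("RB", "RBR", "RBS"):
                    j -= 1
                if j >= lo and toks[j].lower in (set(BE_FORMS) | set(HAVE_FORMS)):
                    t.tag = "VBN"

    def _tag_one(self, t: Token, prev: Token | None, sent_initial: bool) -> str:
        if not t.is_word:
            return "PUNCT"
        w = t.lower
        if t.is_clitic:
            if w in {"'s", "’s"}:
                # possessive after a nominal; contraction of "is" otherwise
                if prev is not None and (prev.tag.startswith("NN") or prev.tag == "PRP"):
                    return "POS"
                return "VBZ"
            if w in {"n't", "n’t"}:
                return "RB"
            return {"'re": "VBP", "'m": "VBP", "'ve": "VBP", "'ll": "MD", "'d": "MD"}.get(
                w.replace("’", "'"), "VB"
            )
        if w.replace(".", "").replace(",", "").isdigit():
            return "CD"
        if w in BE_FORMS:
            return BE_FORMS[w]
        if w in HAVE_FORMS:
            return HAVE_FORMS[w]
        if w in DO_FORMS:
            return DO_FORMS[w]
        if w in MODALS:
            return "MD"
        if w == "to":
            return "TO"
        if w == "there" and prev is None:
            return "EX"
        if w in PRON_POSS:
            return "PRP$"
        if w in PRON_PERS or w == "her":
            return "PRP"
        if w in DETERMINERS:
            return "DT"
        if w in WH_DET:
            return "WDT"
        if w in WH_PRON:
            return "WP"
        if w in WH_ADV:
            return "WRB"
        if w in CCONJS:
            return "CC"
        if w in SCONJS or w in PREPOSITIONS:
            return "IN"
        if w in INTERJECTIONS:
            return "UH"
        if w in ADVERBS:
            return "RB"
        if w in IRREGULAR_VERBS:
            return IRREGULAR_VERBS[w][1]
        if w in IRREGULAR_NOUNS:
            return "NNS"
        if w in BASE_VERBS:
            # base verb unless a determiner/adjective forces a nominal reading
            if prev is not None and prev.tag in ("DT", "PRP$", "JJ", "CD"):
                return "NN"
            if prev is not None and (prev.tag.startswith("NN") or prev.tag == "PRP"):
                return "VBP"
            return "VB" if prev is not None and prev.tag in ("TO", "MD") else "VBP"
        if w in NOUN_EXCEPTIONS:
            return "NN"
        # suffix heuristics
        if w.endswith("ly") and len(w) > 3:
            return "RB"
        if w.endswith("ing") and len(w) > 4:
            return "VBG"
        if w.endswith("ed") and len(w) > 3:
            if prev is not None and prev.lower in (set(BE_FORMS) | set(HAVE_FORMS)):
                return "VBN"
            return "VBD"
        if any(w.endswith(s) for s in _NOMINAL_SUFFIXES):
            return "NN"
        if any(w.endswith(s) for s in _ADJ_SUFFIXES):
            return "JJ"
        if w.endswith("s") and len(w) > 2 and not w.endswith(("ss", "us", "is")):
            if prev is not None and (prev.tag.startswith("NN") or prev.tag == "PRP"):
                return "VBZ"
            return "NNS"
        if not sent_initial and t.surface[:1].isupper():
            return "NNP"
        return "NN"

    # -- lemmatization ------------------------------------------------------

    def _lemma(self, t: Token) -> str:
        w = t.lower
        if t.is_clitic:
            return {"n't": "not", "'s": "'s", "'re": "be", "'m": "be", "'ve": "have",
                    "'ll": "will", "'d": "would"}.get(w.replace("’", "'"), w)
        if w in BE_FORMS:
            return "be"
        if w in HAVE_FORMS:
            return "have"
        if w in DO_FORMS:
            return "do"
        if w in IRREGULAR_VERBS:
            return IRREGULAR_VERBS[w][0]
        if w in IRREGULAR_NOUNS:
            return IRREGULAR_NOUNS[w]
        tag = t.tag
        if tag in ("NNS", "VBZ", "NNPS"):
            return self._strip_s(w)
        if tag in ("VBD", "VBN"):
            return self._strip_ed(w)
        if tag == "VBG":
            return self._strip_suffix(w, "ing")
        return w

    def _strip_s(self, w: str) -> str:
        if w.endswith("ies") and len(w) > 4:
            return w[:-3] + "y"
        if w.endswith(("ches", "shes", "sses", "xes", "zes")):
            return w[:-2]
        if w.endswith("s") and not w.endswith("ss"):
            return w[:-1]
        return w

    def _strip_ed(self, w: str) -> str:
        return self._strip_suffix(w, "ed")

    def _strip_suffix(self, w: str, suf: str) -> str:
        if not w.endswith(suf) or len(w) <= len(suf) + 1:
            return w
        stem = w[: -len(suf)]
        if suf == "ed" and w.endswith("ied") and len(w) > 4:
            return w[:-3] + "y"
        if stem in self._dict or stem in BASE_VERBS:
            return stem
        if stem + "e" in self._dict or stem + "e" in BASE_VERBS:
            return stem + "e"
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
            return stem[:-1]
        # orthographic default: restore silent e after common stems
        if stem.endswith(("at", "iz", "is", "ut", "or", "ir", "v", "c")):
            return stem + "e"
        return stem

    # -- parsing ------------------------------------------------------------

    def _parse_sentence(self, toks: list[Token], lo: int, hi: int) -> None:
        rng = range(lo, hi)

        def nominal(i: int) -> bool:
            return toks[i].pos in ("NOUN", "PROPN", "PRON", "NUM") and toks[i].tag != "PRP$"

        verbs = [i for i in rng if toks[i].pos == "VERB"]
        auxes = [i for i in rng if toks[i].pos == "AUX"]
        if verbs:
            root = verbs[0]
        elif auxes:
            root = auxes[0]
        else:
            nouns = [i for i in rng if nominal(i)]
            root = nouns[-1] if nouns else max(
                (i for i in rng if toks[i].is_word), default=hi - 1
            )
        for i in rng:
            toks[i].dep_relation = "dep"
            toks[i].head_index = root
        toks[root].dep_relation = "ROOT"
        toks[root].head_index = root

        claimed: set[int] = set()  # tokens consumed inside an NP or PP

        def next_noun(start: int, stop: int) -> int | None:
            for j in range(start, stop):
                if toks[j].pos in ("VERB", "AUX"):
                    return None
                if nominal(j):
                    return j
            return None

        # NP-internal attachment
        for i in rng:
            t = toks[i]
            if t.tag == "POS":
                if i - 1 in rng and nominal(i - 1):
                    t.dep_relation, t.head_index = "case", i - 1
                    owner = next_noun(i + 1, hi)
                    if owner is not None:
                        toks[i - 1].dep_relation = "poss"
                        toks[i - 1].head_index = owner
                        claimed.add(i - 1)
                claimed.add(i)
            elif t.tag == "PRP$":
                owner = next_noun(i + 1, hi)
                t.dep_relation = "poss"
                t.head_index = owner if owner is not None else root
                claimed.add(i)
            elif t.pos == "DET":
                owner = next_noun(i + 1, hi)
                t.dep_relation = "det"
                t.head_index = owner if owner is not None else root
                claimed.add(i)
            elif t.pos == "ADJ":
                owner = next_noun(i + 1, hi)
                t.dep_relation = "amod"
                t.head_index = owner if owner is not None else root
                claimed.add(i)
            elif nominal(i) and i + 1 in rng and toks[i + 1].tag != "POS" and \
                    nominal(i + 1) and toks[i].pos in ("NOUN", "PROPN"):
                t.dep_relation, t.head_index = "compound", i + 1
                claimed.add(i)

        # prepositional phrases
        for i in rng:
            if toks[i].pos != "ADP":
                continue
            head = next(
                (j for j in range(i - 1, lo - 1, -1) if toks[j].pos == "VERB"),
                None,
            )
            if head is None:
                head = next(
                    (j for j in range(i - 1, lo - 1, -1)
                     if nominal(j) or toks[j].pos == "AUX"),
                    root,
                )
            toks[i].dep_relation, toks[i].head_index = "prep", head
            j = i + 1
            last_nom = None
            while j < hi and (nominal(j) or toks[j].pos in ("DET", "ADJ", "PART")
                              or toks[j].tag in ("PRP$", "POS")):
                if nominal(j):
                    last_nom = j
                j += 1
            if last_nom is not None:
                toks[last_nom].dep_relation, toks[last_nom].head_index = "pobj", i
                claimed.add(last_nom)

        def heads_of_nps(a: int, b: int) -> list[int]:
            return [i for i in range(a, b) if nominal(i) and i not in claimed]

        # auxiliaries attach to the nearest following main verb
        passive_aux: dict[int, int] = {}
        for i in auxes:
            if i == root and not verbs:
                continue  # copular root
            main = next((v for v in verbs if v > i), root)
            t = toks[i]
            if toks[main].tag == "VBN" and t.lower in BE_FORMS:
                t.dep_relation = "auxpass"
                passive_aux[main] = i
            else:
                t.dep_relation = "aux"
            t.head_index = main

        # subjects
        clause_verbs = verbs if verbs else ([root] if auxes else [])
        prev_boundary = lo
        first_clause = True
        for v in clause_verbs:
            cands = heads_of_nps(prev_boundary, v)
            if cands:
                subj = cands[-1]
                passive = toks[v].tag == "VBN" and v in passive_aux
                toks[subj].dep_relation = "nsubjpass" if passive else "nsubj"
                toks[subj].head_index = v
                claimed.add(subj)
            if not first_clause:
                # a second finite clause: conj if coordinated, parataxis otherwise
                between = range(prev_boundary, v)
                if any(toks[j].pos == "CCONJ" for j in between):
                    toks[v].dep_relation, toks[v].head_index = "conj", root
                elif any(toks[j].pos == "SCONJ" for j in between):
                    toks[v].dep_relation, toks[v].head_index = "advcl", root
                else:
                    toks[v].dep_relation, toks[v].head_index = "parataxis", root
            prev_boundary = v + 1
            first_clause = False

        # objects and predicate nominals
        for k, v in enumerate(clause_verbs):
            stop = clause_verbs[k + 1] if k + 1 < len(clause_verbs) else hi
            for j in range(v + 1, stop):
                if toks[j].pos in ("ADP",):
                    break
                if nominal(j) and j not in claimed:
                    if toks[j].dep_relation in ("dep",):
                        is_cop = toks[v].pos == "AUX"
                        toks[j].dep_relation = "attr" if is_cop else "dobj"
                        toks[j].head_index = v
                        claimed.add(j)
                    break

        # remaining relations
        for i in rng:
            t = toks[i]
            if t.dep_relation != "dep" or i == root:
                continue
            if t.pos == "ADV" or t.tag == "RB":
                target = min(
                    (v for v in (verbs or [root])), key=lambda v: abs(v - i), default=root
                )
                t.dep_relation = "neg" if t.lower in ("not", "n't") else "advmod"
                t.head_index = target
            elif t.pos == "PART" and t.lower in ("not", "n't"):
                t.dep_relation = "neg"
                t.head_index = root
            elif t.pos == "SCONJ":
                target = next((v for v in verbs if v > i), root)
                t.dep_relation, t.head_index = "mark", target
            elif t.pos == "CCONJ":
                t.dep_relation, t.head_index = "cc", root
            elif t.pos == "INTJ":
                t.dep_relation, t.head_index = "intj", root
            elif t.tag == "TO":
                nxt_v = next((v for v in verbs if v > i), None)
                if nxt_v is not None:
                    t.dep_relation, t.head_index = "aux", nxt_v
                    if toks[nxt_v].dep_relation in ("dep", "parataxis"):
                        toks[nxt_v].dep_relation, toks[nxt_v].head_index = "xcomp", root
                else:
                    t.dep_relation, t.head_index = "prep", root
            elif not t.is_word:
                t.dep_relation, t.head_index = "punct", root

    # -- entities -----------------------------------------------------------

    def _ner(self, toks: list[Token]) -> None:
        for t in toks:
            if not t.counts_as_word:
                continue
            if t.lower in GAZETTEER:
                t.entity_label = GAZETTEER[t.lower]
            elif t.tag == "NNP":
                t.entity_label = "Person"
            elif t.tag == "CD":
                t.entity_label = "Quantity"

    # -- entry point --------------------------------------------------------

    def annotate(self, text: RawText) -> AnnotatedDocument:
        text.validate()
        toks = tokenize(text)
        spans = segment_sentences(toks)
        for lo, hi in spans:
            self._tag_sentence(toks, lo, hi)
        for t in toks:
            t.pos = penn_to_upos(t.tag, t.lower)
            t.pos_detail = PENN_DESCRIPTIONS.get(t.tag, t.tag)
            t.lemma = self._lemma(t) if t.is_word else t.surface
            if t.counts_as_word and t.letter_count:
                t.syllables = syllabify(t.lower)
        for lo, hi in spans:
            self._parse_sentence(toks, lo, hi)
        self._ner(toks)
        return AnnotatedDocument(tokens=toks, sentence_spans=spans, language=text.language)
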