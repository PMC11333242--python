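# Methods

This note documents how each measure is computed, the conventions the
package fixes where the underlying formulas leave choices open, what the
synthetic fixture generator does and does not emulate, and the package's
known limitations.

## Tokenization and counting conventions

A *word token* is any token containing at least one letter or digit;
punctuation and symbols never enter word counts. Possessive and
contraction clitics (`'s`, `n't`, `'re`, …) are split into their own
tokens — the possessive clitic is tagged as a particle with the
"Possessive Ending" detail — but are excluded from word, syllable, and
letter counts, and they carry an empty syllable list in the word-label
table. Token indices are 0-based; sentence spans are half-open intervals
that partition the token list. Sentence boundaries are terminal
punctuation (`. ! ? …`) extended through closing quotes/brackets; there is
no abbreviation model, so `e.g.` splits a sentence (a known limitation).

Two character counts are distinguished deliberately: Coleman-Liau uses
*letters only*; the Automated Readability Index uses letters+digits.
Lexical character density uses all non-whitespace characters of word
tokens.

## Annotation backend

All linguistic labels come from a pluggable backend. The default,
bundled backend is a deterministic rule-based English pipeline: a
closed-class lexicon plus suffix heuristics for Penn-style tags, a
rule-based lemmatizer validated against the bundled dictionary, and a
pattern-driven dependency attacher covering the constructions the
measures rely on — possessives (`poss`/`case`), passives
(`nsubjpass`/`auxpass`, detected through *be* + past participle with
intervening adverbs allowed), subjects and objects, prepositional phrases
(`prep`/`pobj`), coordination, subordination markers, and a small
gazetteer-plus-capitalization named-entity tagger. Its output is a pure
function of the input text, so every measure is exactly reproducible.
It is not a statistical parser and will mis-tag open-domain text; for
production analysis of real clinical transcripts the spaCy adapter
(`get_backend(..., name="spacy")`) should be preferred when models are
available. The `precision` flag selects a larger backend model where one
exists; it never changes any formula.

## Syllabification

Vowel-group counting over the orthographic word with corrections: silent
final *-e* (except consonant+*le*), *-ed* syllabic only after *t/d*,
*-es* syllabic only after a sibilant letter, *y* vocalic except
word-initially or after a vowel, *u* after *q* non-vocalic, plus a small
exception list. Boundaries are placed V-CV for single consonants and
VC-CV for clusters. The algorithm is total and deterministic over
alphabetic strings; readability formulas need only the counts, and
boundary placement is a convenience for the word-label table.

## Readability choices

* Only Flesch Reading Ease is capped (to [0, 100]); raw and reported
  values are both returned. No other index is clamped.
* ARI is computed exactly as its printed two-term form by default; the
  conventional −21.43 constant is available via `conventional=True`
  (the two-term form cannot reach the kindergarten anchor score of 1,
  which is why both variants are exposed).
* SMOG uses three ten-sentence samples (beginning/middle/end) when the
  text has ≥ 30 sentences, otherwise all sentences; the 30/sentences
  factor normalizes either way.
* Linsear Write runs on the first 100 word tokens (points scaled to a
  100-word basis for shorter texts); the r ≤ 20 branch (Lw = r/2 − 1)
  applies inclusively at r = 20.
* Difficult and complex words are counted per occurrence, case-folded.
* The bundled easy-word list (`data/easy_words_synthetic.txt`) is a
  constructed common-word list in the Dale-Chall style, not the published
  3000-word list; pass `easy_words=` / `--easy-words` to use a canonical
  resource. The 3.6365 adjustment applies strictly above a 5%
  difficult-word share.
* Grade labels assign boundary values to the upper band (Flesch 90 →
  "5th grade").

## Lexical choices

* Types for the TTR family are case-folded surface forms by default
  (`types="lemma"` switches to lemmas). Logarithms are natural.
* Maas is `ln(ln V)/ln(ln N)` by default, undefined (None) for V or N ≤ e;
  `maas_canonical=True` gives a² = (ln N − ln V)/ln²N.
* MSTTR uses complete segments only (default 100 tokens; the incomplete
  tail is dropped) and reports the mean segment TTR as a 0–1 ratio,
  while TTR itself is on the conventional 0–100 scale.
* The proposition set is {nsubj(pass), csubj, dobj/obj/iobj, acl, advcl,
  relcl, xcomp, ccomp, pobj/obl}; prepositional objects are included so
  that a locative clause ("the cat was on the mat") contributes a
  proposition. Propositions deduplicate on (relation, head lemma,
  dependent lemma); PID is unique propositions per word token (the
  per-word reading matches the standard worked example of 100
  propositions in 1000 words → 0.1).

## Phonology

The bundled G2P backend combines a pronunciation lexicon for frequent
English words with deterministic letter-to-sound rules (digraphs, magic-e,
soft c/g, -ed/-es suffix phonology, word-final s-voicing conditioned on
the preceding segment's voicing). Phoneme sequences are lists of segment
strings — affricates, diphthongs, and length-marked vowels stay single
segments. Stress marks and ties are stripped for counting (configurable
via `PhonemeSequence.segments` vs `.stripped()`). The backend produces a
general phonemic representation, not a speaker-specific transcription, and
its out-of-lexicon pronunciations are approximate; the phonemizer/espeak
adapter is available for users who need broad-coverage transcription.

## Constituents, entities, grammar flags

Noun phrases are maximal nominal-headed subtrees (a nominal linked to a
larger nominal by `poss`/`compound` is not counted separately); verb
phrases are non-auxiliary verbal heads; prepositional phrases are
adpositions heading an object. Entity mentions are maximal runs of
identically labelled tokens, counted per occurrence.

A fragment is a sentence without a finite (or passive-participle)
predicate carrying a subject. A run-on has ≥ 2 independent finite clauses
with neither a coordinating conjunction nor punctuation between them;
clauses introduced by subordinators or wh-words are not independent. The
complex-sentence threshold (≥ 3 subordinate clauses) and the paraphasia
edit-distance radius (≤ 2) are tunable heuristics with those defaults,
not normative definitions. Tokens recognized as named entities are never
flagged as nonwords.

## Edit-distance scoring

The distance is optimal string alignment (restricted Damerau-Levenshtein):
unit-cost insertions, deletions, substitutions, adjacent transpositions,
no substring edited twice. The backtrace resolves ties in the fixed order
match > substitution > transposition > deletion > insertion from the
sequence ends, making the per-type decomposition deterministic; the counts
always sum to the distance, and swapping target and response swaps
insertions with deletions. The composite score is 1 − d/max(|t|, |r|) in
letters (word mode) or phonemes (nonword/phoneme modes). Word-mode
comparison is case-folded and accent-preserving. "Inversions" on clinical
scoring sheets are exported as an alias column of substitutions: the
four operation types of the scorer must cover the four clinically named
error categories, and substitution is the reading consistent with the
phonology scorer's explicit list.

## Synthetic fixtures

`generate_fixture` builds texts from a closed vocabulary with known
syllabification, so word/sentence/syllable/passive/difficult ground truth
is exact by construction rather than re-derived through the pipeline under
test. Sentences are simple SVO clauses; passives use the
*was + participle + by* frame; "difficult" words are pronounceable nonce
nouns absent from the bundled wordlists. `build_pid_document` constructs a
document with an exact proposition budget (unique transitive clauses plus
proposition-free interjection padding).

What the fixtures do **not** emulate: disfluencies, ungrammatical or
fragmentary clinical speech, orthographic errors, dialogue structure, or
vocabulary outside the closed pools. Passing tests therefore demonstrate
correctness of the measurement pipeline on well-formed input, not tagger
robustness on real patient transcripts — the latter depends on the chosen
annotation backend.

Problem sizes used by the test and acceptance suites (chosen as the
package's own desk-scale defaults): fixture corpora of 3–10 sentences,
the 1000-word idea-density document, exhaustive edit-distance checks over
three-letter strings up to length 4 plus 10⁴ random longer pairs, and
50-tuple formula oracle suites.

## Numerical and degenerate-input conventions

Division-guarded measures raise `EmptyInput` on empty documents rather
than returning NaN. Maas/MSTTR/Herdan return None where undefined.
Batch analysis records per-file failures as error rows with explicitly
null measures and never silently drops a row; pair scoring flags empty
cells and continues. All randomness (fixture generation only) flows
through an explicit seed; regenerating with the same seed is
byte-identical.

## Known limitations

* The rule backend is English-only; other languages require the spaCy
  adapter and an installed model (`UnsupportedLanguage` otherwise).
* No abbreviation-aware sentence splitting.
* The bundled wordlists are constructed, not the published clinical
  resources; scores depending on them (Dale-Chall, nonword flags) shift
  with the list supplied.
* G2P fallback rules cover regular English letter-to-sound patterns only;
  irregular out-of-lexicon words receive regularized pronunciations.
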