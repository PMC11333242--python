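# obai-metrics

Quantitative language measurement for clinical assessment and research.

Clinicians and researchers working with acquired and developmental language
disorders (aphasia, primary progressive aphasia, mild cognitive impairment,
developmental language disorder) routinely need objective, reproducible
measures of a patient's written or transcribed language: how readable a text
is, how lexically diverse, how dense in ideas, which grammatical
constructions it uses, and how far a spelling or repetition response deviates
from its target. This package computes those measures from plain text and
target/response spreadsheets, deterministically and offline.

## What it computes

**Readability** — the ten standard indices with their published
coefficients, e.g. Flesch Reading Ease

> FRE = 206.835 − 1.015 · (W/S) − 84.6 · (Syll/W)

(reported capped at 100), Flesch-Kincaid grade
0.39·(W/S) + 11.8·(Syll/W) − 15.59, Gunning Fog
0.4·[(W/S) + 100·complex/W], Coleman-Liau 0.0588·L − 0.296·S − 15.8,
Automated Readability Index, SMOG
1.0430·√(polysyllables·30/S) + 3.1291, Linsear Write, passive-sentence
percentage, the Dale-Chall score
0.1579·(100·difficult/W) + 0.0496·(W/S) with its 3.6365 adjustment above
5% difficult words, and the difficult-word count — plus the grade-level
interpretation tables for Flesch and Coleman-Liau.

**Lexical** — character/word/sentence counts, function- vs content-word
partition (the agrammatism-sensitive split), propositional idea density
(PID = unique propositions / words, propositions read off the dependency
parse: subjects, objects, clausal modifiers and complements, relative
clauses, prepositional objects), and the type-token-ratio family:
TTR = 100·V/N, CTTR = V/√(2N), Maas, MSTTR over 100-token segments, and
Herdan's C = ln V / ln N.

**Phonology** — grapheme-to-phoneme conversion to IPA segments (with
context-sensitive rules such as word-final /s/ → /z/ voicing after voiced
segments), syllable counts, syllable/word ratio, and phoneme distributions.

**Morphosyntax & semantics** — POS distributions, constituent counts (noun
/ verb / prepositional phrases derived from the dependency parse),
named-entity distributions, and a per-word labeling table (word,
syllables, lemma, POS, POS detail, dependency).

**Grammar flags** — heuristic detection of fragments, run-on sentences,
overly complex sentences, and dictionary-based nonword candidates
(phonemic paraphasias vs neologisms, hapax legomena).

**Clinical scoring** — restricted Damerau-Levenshtein (optimal string
alignment) edit scripts between targets and responses, letter-wise for
words and phoneme-wise for non-words and phonology scoring, with the
composite similarity 1 − d/max(|t|,|r|) and a per-error-type decomposition
(insertions, deletions, substitutions, transpositions) that always sums to
the distance.

Annotation (POS, lemmas, dependencies, entities) runs through a pluggable
backend. The default is a bundled deterministic rule-based English backend
(no model downloads, identical output everywhere); an adapter for spaCy
pipelines is included for users who have the models installed.

## Worked example

```python
import obai_metrics as om
from obai_metrics.io_utils import load_easy_words

text = ("The ball was thrown by John. John ran across the garden. "
        "The little dog saw the beautiful caterpillar. The weather today is sunny.")
doc = om.annotate(text)
r = om.readability_report(doc, easy_words=load_easy_words())
lex = om.lexical_report(doc)
```

prints (via the fields shown):

```
flesch_reading_ease       75.938 -> 7th grade / Fairly easy to read
flesch_kincaid_grade      4.096
gunning_fog               5.778
coleman_liau              5.64  -> 5th grade and below / Very easy
passive_percent           25.0
dale_chall (raw, adj)     1.6582 5.2947
words/sentences/syllables 23 4 34
pid                       0.3043 ( 7 unique propositions )
ttr / cttr                78.26 2.654
function/content          9 14
```

One of the four sentences is passive (`passive_percent` 25.0); the two
out-of-list words push the difficult-word share above 5%, so the adjusted
Dale-Chall score is the raw score plus exactly 3.6365. PID 0.304 means the
23 words express 7 unique dependency propositions.

Scoring a spelling response:

```python
row = om.spell_score_word("from", "form")
# row.distance == 1, row.transpositions == 1, row.similarity == 0.75
```

The command-line tools mirror the library: `obai-metrics readability
FILE`, `obai-metrics lexical|ipa|phonology|label|grammar|batch`, and
`obai-score spelling|phonology PAIRS.csv` for spreadsheet scoring.

## Documentation

`docs/methods.md` describes the measurement procedures, their assumptions,
the tunable parameters, the synthetic fixture generator, and known
limitations.
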