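"""Target/response scoring for the spelling and phonology applications.

The distance is the restricted (optimal string alignment) Damerau-
Levenshtein distance: unit-cost insertions, deletions, substitutions, and
adjacent transpositions, with no substring edited twice.  The full edit
script is recovered by backtracking; at equal cost the backtrace prefers
match > substitution > transposition > deletion > insertion, scanning from
the sequence ends, so per-type error counts are deterministic and
reproducible.

Three scoring modes share the mechanics:

* ``word``       — letter sequences, case-folded, accents preserved;
* ``nonword``    — both strings are converted to IPA phoneme sequences
  first (non-words have no standardized orthography, so writers spell from
  their phonemic buffer; two homophonic spellings score distance 0);
* ``phoneme``    — identical to nonword mode; used by the phonology scorer.

The composite score is the normalized similarity
``1 - distance / max(len(target), len(response))`` in [0, 1], measured in
letters (word mode) or phonemes (other modes).  "Inversions" in clinical
scoring sheets are reported via a column alias of substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import MissingValue, SchemaError
from .phonology import G2PBackend, get_g2p

Symbols = Union[str, Sequence[str]]


@dataclass
class EditOp:
    op: str  # match | substitution | insertion | deletion | transposition
    target_index: Optional[int]
    response_index: Optional[int]
    target_symbols: tuple[str, ...] = ()
    response_symbols: tuple[str, ...] = ()


@dataclass
class EditScript:
    operations: list[EditOp]
    distance: int

    @property
    def counts(self) -> dict[str, int]:
        c = {"insertions": 0, "deletions": 0, "substitutions": 0, "transpositions": 0}
        key = {"insertion": "insertions", "deletion": "deletions",
               "substitution": "substitutions", "transposition": "transpositions"}
        for op in self.operations:
            if op.op in key:
                c[key[op.op]] += 1
        return c


def _dp_table(a: Sequence[str], b: Sequence[str]) -> list[list[int]]:
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            best = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
                and a[i - 1] != b[j - 1]
            ):
                best = min(best, d[i - 2][j - 2] + 1)
            d[i][j] = best
    return d


def osa_distance(target: Symbols, response: Symbols) -> int:
    """Restricted Damerau-Levenshtein distance between two symbol sequences."""
    a = list(target)
    b = list(response)
    return _dp_table(a, b)[len(a)][len(b)]


def edit_script(target: Symbols, response: Symbols) -> EditScript:
    """Minimal edit script turning ``target`` into ``response``.

    Deterministic tie-breaking during the backtrace (see module docstring)
    fixes the per-type decomposition; the counts always sum to the distance.
    """
    a = list(target)
    b = list(response)
    d = _dp_table(a, b)
    ops: list[EditOp] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        cur = d[i][j]
        if i > 0 and j > 0 and a[i - 1] == b[j - 1] and cur == d[i - 1][j - 1]:
            ops.append(EditOp("match", i - 1, j - 1, (a[i - 1],), (b[j - 1],)))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and a[i - 1] != b[j - 1] and cur == d[i - 1][j - 1] + 1:
            ops.append(EditOp("substitution", i - 1, j - 1, (a[i - 1],), (b[j - 1],)))
            i, j = i - 1, j - 1
        elif (
            i > 1
            and j > 1
            and a[i - 1] == b[j - 2]
            and a[i - 2] == b[j - 1]
            and a[i - 1] != b[j - 1]
            and cur == d[i - 2][j - 2] + 1
        ):
            ops.append(
                EditOp("transposition", i - 2, j - 2,
                       (a[i - 2], a[i - 1]), (b[j - 2], b[j - 1]))
            )
            i, j = i - 2, j - 2
        elif i > 0 and cur == d[i - 1][j] + 1:
            ops.append(EditOp("deletion", i - 1, None, (a[i - 1],), ()))
            i -= 1
        else:
            ops.append(EditOp("insertion", None, j - 1, (), (b[j - 1],)))
            j -= 1
    ops.reverse()
    return EditScript(operations=ops, distance=d[len(a)][len(b)])


@dataclass
class ScoreRow:
    target: str
    response: str
    mode: str
    distance: Optional[int] = None
    similarity: Optional[float] = None
    insertions: Optional[int] = None
    deletions: Optional[int] = None
    substitutions: Optional[int] = None
    transpositions: Optional[int] = None
    error: str = ""

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["inversions"] = self.substitutions  # clinical-sheet alias
        return d


def _score_sequences(
    target: str, response: str, a: Sequence[str], b: Sequence[str], mode: str
) -> ScoreRow:
    script = edit_script(a, b)
    denom = max(len(a), len(b))
    similarity = 1.0 - script.distance / denom if denom else 1.0
    c = script.counts
    return ScoreRow(
        target=target, response=response, mode=mode,
        distance=script.distance, similarity=similarity,
        insertions=c["insertions"], deletions=c["deletions"],
        substitutions=c["substitutions"], transpositions=c["transpositions"],
    )


def _clean(value: Optional[str], which: str) -> str:
    if value is None or not str(value).strip() or str(value).lower() == "nan":
        raise MissingValue(f"empty {which} cell")
    return str(value).strip()


def spell_score_word(target: str, response: str, language: str = "en") -> ScoreRow:
    """Letter-to-letter spelling score (case-folded, accents preserved)."""
    t = _clean(target, "target").lower()
    r = _clean(response, "response").lower()
    return _score_sequences(target.strip(), response.strip(), list(t), list(r), "word")


def spell_score_nonword(
    target: str,
    response: str,
    language: str = "en",
    backend: Optional[G2PBackend] = None,
) -> ScoreRow:
    """Non-word spelling score over IPA phoneme sequences."""
    t = _clean(target, "target")
    r = _clean(response, "response")
    backend = backend or get_g2p(language)
    return _score_sequences(
        t, r, backend.convert(t.lower()), backend.convert(r.lower()), "nonword"
    )


def phonology_score(
    target: str,
    response: str,
    language: str = "en",
    backend: Optional[G2PBackend] = None,
) -> ScoreRow:
    """Phonemic score: IPA conversion then the phoneme-level edit script."""
    row = spell_score_nonword(target, response, language, backend)
    row.mode = "phoneme"
    return row


_MODE_FN = {
    "word": spell_score_word,
    "nonword": spell_score_nonword,
    "phoneme": phonology_score,
}


def batch_score(
    table: Union[pd.DataFrame, str],
    mode: str = "word",
    language: str = "en",
    target_col: str = "target",
    response_col: str = "response",
    backend: Optional[G2PBackend] = None,
) -> tuple[pd.DataFrame, dict]:
    """Score every target/response row of a pairs table.

    Returns ``(scored table, summary)``.  Rows with a missing cell are kept,
    flagged in the ``error`` column, and excluded from the summary means.
    Output preserves input order and adds the score columns (including the
    ``inversions`` alias of substitutions).
    """
    if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
        from .io_utils import read_pairs_table

        table = read_pairs_table(table)
    for col in (target_col, response_col):
        if col not in table.columns:
            raise SchemaError(f"pairs table is missing required column {col!r}")
    if mode not in _MODE_FN:
        raise SchemaError(f"unknown scoring mode {mode!r}")
    kwargs = {"backend": backend} if mode in ("nonword", "phoneme") else {}
    rows = []
    for _, rec in table.iterrows():
        tgt, rsp = rec[target_col], rec[response_col]
        try:
            row = _MODE_FN[mode](tgt, rsp, language, **kwargs)
        except MissingValue as exc:
            row = ScoreRow(
                target="" if pd.isna(tgt) else str(tgt),
                response="" if pd.isna(rsp) else str(rsp),
                mode=mode, error=str(exc),
            )
        rows.append(row.to_dict())
    out = pd.DataFrame(rows)
    scored = out[out["error"] == ""]
    summary = {
        "n_rows": len(out),
        "n_scored": len(scored),
        "n_flagged": int((out["error"] != "").sum()),
        "mean_distance": float(scored["distance"].mean()) if len(scored) else None,
        "mean_similarity": float(scored["similarity"].mean()) if len(scored) else None,
    }
    return out, summary
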