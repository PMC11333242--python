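"""Edit-distance scoring against an independent oracle, plus metric and
decomposition properties."""

from functools import lru_cache
from itertools import product

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import obai_metrics as om
from obai_metrics.clinical_scoring import batch_score, edit_script, osa_distance
from obai_metrics.errors import SchemaError


# ---------------------------------------------------------------------------
# independent oracle: recursive optimal-string-alignment dynamic program,
# returning both the distance and the set of optimal operation-count vectors
# (insertions, deletions, substitutions, transpositions)
# ---------------------------------------------------------------------------

def oracle_distance(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                   d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
        if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1] and a[i - 1] != b[j - 1]):
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def oracle_count_vectors(a: str, b: str) -> tuple[int, frozenset]:
    """Distance and every optimal (ins, del, sub, trans) decomposition."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0:
            return j, frozenset({(j, 0, 0, 0)})
        if j == 0:
            return i, frozenset({(0, i, 0, 0)})
        options = []
        dd, vs = f(i - 1, j - 1)
        if a[i - 1] == b[j - 1]:
            options.append((dd, vs))
        else:
            options.append((dd + 1, frozenset(
                (x, y, z + 1, t) for x, y, z, t in vs)))
        dd, vs = f(i - 1, j)
        options.append((dd + 1, frozenset((x, y + 1, z, t) for x, y, z, t in vs)))
        dd, vs = f(i, j - 1)
        options.append((dd + 1, frozenset((x + 1, y, z, t) for x, y, z, t in vs)))
        if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1] and a[i - 1] != b[j - 1]):
            dd, vs = f(i - 2, j - 2)
            options.append((dd + 1, frozenset(
                (x, y, z, t + 1) for x, y, z, t in vs)))
        best = min(d for d, _ in options)
        merged = frozenset().union(*(v for d, v in options if d == best))
        return best, merged

    return f(len(a), len(b))


def all_strings(alphabet: str, max_len: int):
    for n in range(max_len + 1):
        for tup in product(alphabet, repeat=n):
            yield "".join(tup)


class TestEditScriptExamples:
    def test_identity(self):
        s = edit_script("boat", "boat")
        assert s.distance == 0 and all(v == 0 for v in s.counts.values())

    def test_adjacent_transposition(self):
        s = edit_script("cat", "cta")
        assert s.distance == 1 and s.counts["transpositions"] == 1

    def test_deletion(self):
        s = edit_script("house", "hose")
        assert s.distance == 1 and s.counts["deletions"] == 1

    def test_insertions_from_empty(self):
        s = edit_script("", "ab")
        assert s.distance == 2 and s.counts["insertions"] == 2

    def test_from_form_transposition(self):
        s = edit_script("from", "form")
        assert s.distance == 1 and s.counts["transpositions"] == 1

    def test_yacht_yat_two_deletions(self):
        s = edit_script("yacht", "yat")
        assert s.distance == 2 and s.counts["deletions"] == 2

    def test_nonadjacent_swap_is_two_substitutions(self):
        s = edit_script(list("kæt"), list("tæk"))
        assert s.distance == 2 and s.counts["substitutions"] == 2


class TestOracleEquivalence:
    def test_distance_matches_oracle_exhaustively(self):
        strings = list(all_strings("abc", 4))
        for a in strings:
            for b in strings:
                assert osa_distance(a, b) == oracle_distance(a, b), (a, b)

    def test_decomposition_is_an_optimal_vector(self):
        import random

        rng = random.Random(99)
        strings = list(all_strings("abc", 5))
        for _ in range(1500):
            a, b = rng.choice(strings), rng.choice(strings)
            dist, vectors = oracle_count_vectors(a, b)
            s = edit_script(a, b)
            c = s.counts
            vec = (c["insertions"], c["deletions"], c["substitutions"],
                   c["transpositions"])
            assert s.distance == dist, (a, b)
            assert sum(vec) == dist, (a, b)
            assert vec in vectors, (a, b, vec, vectors)


class TestMetricProperties:
    strings = st.text(alphabet="abc", max_size=5)

    @given(strings, strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_symmetry_and_identity(self, a, b):
        assert osa_distance(a, b) == osa_distance(b, a)
        assert (osa_distance(a, b) == 0) == (a == b)

    @given(strings, strings, strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_triangle_inequality(self, a, b, c):
        assert osa_distance(a, c) <= osa_distance(a, b) + osa_distance(b, c)

    @given(strings, strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_swap_exchanges_insertions_and_deletions(self, a, b):
        fwd = edit_script(a, b).counts
        rev = edit_script(b, a).counts
        assert fwd["insertions"] == rev["deletions"]
        assert fwd["deletions"] == rev["insertions"]
        assert fwd["substitutions"] == rev["substitutions"]
        assert fwd["transpositions"] == rev["transpositions"]

    @given(strings, strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_counts_sum_to_distance(self, a, b):
        s = edit_script(a, b)
        assert sum(s.counts.values()) == s.distance

    @given(strings, strings)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_applying_script_reconstructs_response(self, a, b):
        s = edit_script(a, b)
        out = []
        for op in s.operations:
            if op.op in ("match", "substitution"):
                out.append(op.response_symbols[0])
            elif op.op == "transposition":
                out.extend(op.response_symbols)
            elif op.op == "insertion":
                out.append(op.response_symbols[0])
            # deletions emit nothing
        assert "".join(out) == b


class TestScoreRows:
    def test_word_mode_similarity(self):
        row = om.spell_score_word("boat", "boat")
        assert row.similarity == 1.0 and row.distance == 0

    def test_word_mode_case_folded(self):
        assert om.spell_score_word("Boat", "boat").distance == 0

    def test_nonword_mode_homophones_score_zero_distance(self):
        row = om.spell_score_nonword("dake", "daik")
        assert row.distance == 0 and row.similarity == 1.0
        # word mode sees the orthographic difference
        assert om.spell_score_word("dake", "daik").distance > 0

    def test_phoneme_substitution(self):
        row = om.phonology_score("dake", "take")
        assert row.distance == 1 and row.substitutions == 1

    def test_phoneme_insertion(self):
        row = om.phonology_score("cat", "cats")
        assert row.distance == 1 and row.insertions == 1

    def test_similarity_normalization(self):
        row = om.spell_score_word("yacht", "yat")
        assert row.similarity == pytest.approx(1 - 2 / 5)


class TestBatchScore:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {"target": ["boat", "from", "yacht"], "response": ["boat", "form", ""]}
        )

    def test_rows_preserved_and_flagged(self):
        out, summary = batch_score(self._table())
        assert len(out) == 3
        assert summary["n_scored"] == 2 and summary["n_flagged"] == 1
        assert out.loc[2, "error"] != ""

    def test_identical_pairs_mean_similarity_one(self):
        table = pd.DataFrame({"target": ["cat"] * 3, "response": ["cat"] * 3})
        _, summary = batch_score(table)
        assert summary["mean_similarity"] == pytest.approx(1.0)

    def test_rerun_identical(self):
        a, _ = batch_score(self._table())
        b, _ = batch_score(self._table())
        assert a.equals(b)

    def test_inversions_alias_mirrors_substitutions(self):
        out, _ = batch_score(pd.DataFrame({"target": ["cat"], "response": ["bat"]}))
        assert out.loc[0, "inversions"] == out.loc[0, "substitutions"] == 1

    def test_missing_column_schema_error(self):
        with pytest.raises(SchemaError):
            batch_score(pd.DataFrame({"target": ["a"]}))

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "pairs.csv"
        self._table().to_csv(path, index=False)
        out, summary = batch_score(path)
        assert summary["n_rows"] == 3
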