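"""Lexical counts, function/content partition, propositions/PID, and the
TTR family against hand-evaluated values."""

import math
import random

import pytest

import obai_metrics as om
from obai_metrics.errors import EmptyInput
from obai_metrics.lexical import (
    basic_counts,
    diversity,
    extract_propositions,
    function_content_partition,
    lexical_report,
)


class TestBasicCounts:
    def test_characters_and_density(self, annotate):
        chars, density, words, sentences, msl = basic_counts(annotate("cat sat"))
        assert (chars, words) == (6, 2)
        assert density == pytest.approx(3.0)

    def test_mean_sentence_length(self, annotate):
        doc = annotate("one two three four five. six seven eight nine ten.")
        _, _, words, sentences, msl = basic_counts(doc)
        assert (words, sentences) == (10, 2)
        assert msl == pytest.approx(5.0)

    def test_single_letter_word(self, annotate):
        chars, density, *_ = basic_counts(annotate("a"))
        assert density == pytest.approx(1.0)


class TestFunctionContent:
    def test_partition_counts(self, annotate):
        fn, fnp, ct, ctp = function_content_partition(annotate("The cat sat"))
        assert (fn, ct) == (1, 2)
        assert fnp == pytest.approx(1 / 3)
        assert ctp == pytest.approx(2 / 3)

    def test_proportions_sum_to_one_on_fixtures(self):
        for seed in range(4):
            text, _ = om.generate_fixture(om.FixtureSpec(n_sentences=3, seed=seed))
            fn, fnp, ct, ctp = function_content_partition(om.annotate(text))
            assert fnp + ctp == pytest.approx(1.0)
            words = len(om.annotate(text).word_tokens())
            assert fn + ct == words


class TestPropositions:
    def test_worked_example_two_propositions(self, cat_mat_doc):
        assert len(extract_propositions(cat_mat_doc)) == 2

    def test_interjection_only_text_has_none(self, annotate):
        assert extract_propositions(annotate("Yes.")) == set()

    def test_repetition_does_not_add_propositions(self, annotate):
        once = extract_propositions(annotate("The cat sat."))
        twice = extract_propositions(annotate("The cat sat. The cat sat."))
        assert once == twice

    def test_pid_worked_example_fraction(self, cat_mat_doc):
        assert om.pid(cat_mat_doc) == pytest.approx(2 / 6, abs=1e-9)

    def test_pid_halves_under_self_concatenation(self, annotate):
        text = "The cat sat on the mat."
        single = om.pid(annotate(text))
        doubled = om.pid(annotate(text + " " + text))
        assert doubled == pytest.approx(single / 2)


class TestDiversity:
    def test_all_distinct_ttr_100(self):
        ttr, *_ = diversity([f"w{i}" for i in range(10)])
        assert ttr == pytest.approx(100.0)

    def test_cttr_hand_value(self):
        _, cttr, *_ = diversity([f"w{i}" for i in range(10)])
        assert cttr == pytest.approx(10 / math.sqrt(20), abs=1e-9)

    def test_herdan_hand_value(self):
        tokens = ["a", "b", "c", "d", "e", "a", "b", "c", "d", "e"]
        *_, herdan = diversity(tokens)
        assert herdan == pytest.approx(math.log(5) / math.log(10), abs=1e-9)

    def test_msttr_mean_of_segments(self):
        seg1 = [f"u{i}" for i in range(80)] + ["u0"] * 20          # TTR 0.8
        seg2 = [f"v{i}" for i in range(60)] + ["v0"] * 40          # TTR 0.6
        _, _, _, msttr, _ = diversity(seg1 + seg2, segment_size=100)
        assert msttr == pytest.approx(0.7, abs=1e-9)

    def test_maas_undefined_markers(self):
        *_, maas, _, _ = diversity(["a", "b"])
        assert maas is None

    def test_maas_printed_vs_canonical(self):
        tokens = [f"w{i % 7}" for i in range(40)]
        v, n = 7, 40
        *_, maas, _, _ = diversity(tokens)
        assert maas == pytest.approx(math.log(math.log(v)) / math.log(math.log(n)), abs=1e-9)
        *_, maas_c, _, _ = diversity(tokens, maas_canonical=True)
        assert maas_c == pytest.approx((math.log(n) - math.log(v)) / math.log(n) ** 2, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInput):
            diversity([])

    def test_ttr_permutation_invariant_msttr_of_uniform_segments(self):
        rng = random.Random(5)
        tokens = [f"w{i % 10}" for i in range(100)]
        shuffled = tokens[:]
        rng.shuffle(shuffled)
        assert diversity(tokens)[0] == diversity(shuffled)[0]
        # every segment with identical type counts: MSTTR equals that TTR
        seg = [f"s{i}" for i in range(50)] + ["s0"] * 50
        _, _, _, msttr, _ = diversity(seg * 2, segment_size=100)
        assert msttr == pytest.approx(0.5)

    def test_herdan_bounds_random_token_lists(self):
        rng = random.Random(9)
        for _ in range(25):
            n = rng.randint(2, 200)
            v_target = rng.randint(2, n)
            tokens = [f"t{i % v_target}" for i in range(n)]
            *_, herdan = diversity(tokens)
            assert 0 < herdan <= 1

    def test_oracle_suite_random_token_lists(self):
        """The five diversity measures agree with direct evaluations."""
        rng = random.Random(2024)
        for _ in range(50):
            n = rng.randint(4, 300)
            tokens = [f"t{rng.randint(0, n // 2)}" for _ in range(n)]
            v = len(set(tokens))
            ttr, cttr, maas, msttr, herdan = diversity(tokens, segment_size=50)
            assert ttr == pytest.approx(100 * v / n, abs=1e-9)
            assert cttr == pytest.approx(v / math.sqrt(2 * n), abs=1e-9)
            assert herdan == pytest.approx(math.log(v) / math.log(n), abs=1e-9)
            if v > math.e:
                assert maas == pytest.approx(
                    math.log(math.log(v)) / math.log(math.log(n)), abs=1e-9)
            segs = [tokens[i:i + 50] for i in range(0, n - 49, 50)]
            if segs:
                assert msttr == pytest.approx(
                    sum(len(set(s)) / 50 for s in segs) / len(segs), abs=1e-9)
            else:
                assert msttr is None


class TestLexicalReport:
    def test_report_consistency(self, annotate):
        doc = annotate("The cat sat on the mat. The dog saw the cat.")
        rep = lexical_report(doc)
        assert rep.function_word_count + rep.content_word_count == rep.words
        assert rep.function_word_proportion + rep.content_word_proportion == pytest.approx(1.0)
        assert rep.pid == pytest.approx(rep.unique_propositions / rep.words)
        assert 0 <= rep.ttr <= 100
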