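"""Readability formulas against hand-evaluated values and an independent
spreadsheet-style oracle."""

import math
import random

import pytest

import obai_metrics as om
from obai_metrics.errors import EmptyInput, MissingResource, UnsupportedMeasure
from obai_metrics.readability import (
    ReadabilityCounts,
    automated_readability_index,
    coleman_liau,
    dale_chall,
    difficult_words,
    flesch_kincaid_grade,
    flesch_reading_ease,
    grade_label,
    gunning_fog,
    linsear_write,
    passive_percent,
    smog,
)


def make_counts(words, sentences, syllables, letters=None, chars=None,
                complex_words=0, difficult=None):
    letters = letters if letters is not None else words * 4
    return ReadabilityCounts(
        word_count=words, sentence_count=sentences, syllable_count=syllables,
        letter_count=letters, character_count=chars if chars is not None else letters,
        complex_word_count=complex_words, polysyllable_count=complex_words,
        difficult_word_count=difficult,
    )


class TestFormulaExamples:
    def test_flesch_single_easy_word_capped(self):
        raw, capped = flesch_reading_ease(make_counts(1, 1, 1))
        assert raw == pytest.approx(121.22, abs=1e-9)
        assert capped == 100.0

    def test_flesch_hand_value(self):
        raw, _ = flesch_reading_ease(make_counts(20, 2, 30))
        assert raw == pytest.approx(69.785, abs=1e-9)

    def test_flesch_kincaid_values(self):
        assert flesch_kincaid_grade(make_counts(1, 1, 1)) == pytest.approx(-3.40, abs=1e-9)
        assert flesch_kincaid_grade(make_counts(20, 1, 30)) == pytest.approx(9.91, abs=1e-9)

    def test_gunning_fog_values(self):
        assert gunning_fog(make_counts(10, 1, 10)) == pytest.approx(4.0)
        assert gunning_fog(make_counts(10, 1, 16, complex_words=2)) == pytest.approx(12.0)

    def test_coleman_liau_values(self):
        assert coleman_liau(make_counts(20, 2, 30, letters=100)) == pytest.approx(10.64, abs=1e-9)
        assert coleman_liau(make_counts(1, 1, 1, letters=1)) == pytest.approx(-39.52, abs=1e-9)

    def test_ari_values(self):
        assert automated_readability_index(make_counts(1, 1, 1, chars=1)) == pytest.approx(5.21)
        c = make_counts(20, 1, 30, chars=100)
        assert automated_readability_index(c) == pytest.approx(33.55)
        assert automated_readability_index(c, conventional=True) == pytest.approx(33.55 - 21.43)

    def test_smog_values(self):
        assert smog(make_counts(300, 30, 300)) == pytest.approx(3.1291)
        assert smog(make_counts(300, 30, 400, complex_words=30)) == pytest.approx(
            1.0430 * math.sqrt(30.0) + 3.1291
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(EmptyInput):
            flesch_reading_ease(make_counts(0, 1, 0))


class TestLinsear:
    @staticmethod
    def _doc(sentences):
        return om.annotate(" ".join(sentences))

    def test_all_easy_words_ten_sentences(self):
        # 100 monosyllabic words in 10 sentences: r = 10 <= 20, Lw = 4.0
        sent = "the cat saw the dog by the mat the sun."
        doc = self._doc([sent] * 10)
        assert linsear_write(doc) == pytest.approx(4.0)

    def test_hard_words_push_over_twenty(self):
        # 4 sentences x (20 easy + 5 three-syllable) = 140 points, r = 35
        sent = " ".join(["cat"] * 20 + ["banana"] * 5) + "."
        doc = self._doc([sent] * 4)
        assert linsear_write(doc) == pytest.approx(17.5)

    def test_boundary_r_equals_twenty_uses_lower_branch(self):
        # 100 easy words in 5 sentences: r = 20 -> Lw = 20/2 - 1 = 9.0
        sent = " ".join(["cat"] * 20) + "."
        doc = self._doc([sent] * 5)
        assert linsear_write(doc) == pytest.approx(9.0)


class TestPassivePercent:
    def test_half_passive(self, annotate):
        doc = annotate(
            "The ball was thrown by John. John threw the ball. "
            "The house was decorated. The dog barked."
        )
        assert passive_percent(doc) == pytest.approx(50.0)

    def test_all_active_is_zero(self, annotate):
        assert passive_percent(annotate("John threw the ball. The dog barked.")) == 0.0

    def test_two_sentence_contrast(self, annotate):
        doc = annotate("The ball was thrown by John. John threw the ball.")
        assert passive_percent(doc) == pytest.approx(50.0)


class TestDaleChall:
    def test_all_easy(self):
        raw, adj = dale_chall(make_counts(10, 1, 10, difficult=0))
        assert raw == pytest.approx(0.496, abs=1e-9)
        assert adj == raw

    def test_adjustment_applied_above_five_percent(self):
        raw, adj = dale_chall(make_counts(20, 2, 30, difficult=4))
        assert raw == pytest.approx(3.654, abs=1e-9)
        assert adj == pytest.approx(7.2905, abs=1e-9)
        assert adj - raw == pytest.approx(3.6365, abs=1e-12)

    def test_missing_wordlist(self):
        with pytest.raises(MissingResource):
            dale_chall(make_counts(10, 1, 10, difficult=None))

    def test_difficult_words_counts_per_occurrence(self, annotate):
        doc = annotate("zyx zyx")
        assert difficult_words(doc, frozenset({"the", "cat"})) == 2
        doc2 = annotate("the cat purred")
        assert difficult_words(doc2, frozenset({"the", "cat"})) == 1


class TestGradeLabels:
    @pytest.mark.parametrize(
        "measure,score,label",
        [
            ("flesch_reading_ease", 95, "5th grade / Very easy to read"),
            ("flesch_reading_ease", 90, "5th grade / Very easy to read"),
            ("flesch_reading_ease", 55, "10th to 12th grade / Fairly difficult to read"),
            ("coleman_liau", 17, "Professional / Very hard"),
            ("coleman_liau", 6, "6th grade / Easy to read"),
            ("coleman_liau", 3, "5th grade and below / Very easy"),
        ],
    )
    def test_band_lookup(self, measure, score, label):
        assert grade_label(measure, score) == label

    def test_unknown_measure(self):
        with pytest.raises(UnsupportedMeasure):
            grade_label("smog", 8)


class TestSentenceExamples:
    def test_simple_sentence_scores_high_on_flesch(self, annotate):
        report = om.readability_report(annotate("The dog sleeps in the bedroom."))
        assert report.flesch_reading_ease >= 90

    def test_complex_sentence_scores_above_grade_12(self, annotate):
        report = om.readability_report(
            annotate("The industrious professor assessed all student assignments diligently.")
        )
        assert report.flesch_kincaid_grade > 12

    def test_weather_sentence_fog(self, annotate):
        report = om.readability_report(annotate("The weather today is sunny."))
        assert report.gunning_fog == pytest.approx(2.0)


class TestInvariants:
    def test_flesch_capped_and_raw_agree_below_cap(self):
        raw, capped = flesch_reading_ease(make_counts(20, 2, 30))
        assert raw == capped

    def test_syllables_move_flesch_and_fk_in_opposite_directions(self):
        rng = random.Random(7)
        for _ in range(25):
            w = rng.randint(5, 200)
            s = rng.randint(1, max(1, w // 5))
            syl = rng.randint(w, 3 * w)
            lo = make_counts(w, s, syl)
            hi = make_counts(w, s, syl + rng.randint(1, 20))
            assert flesch_reading_ease(hi)[0] < flesch_reading_ease(lo)[0]
            assert flesch_kincaid_grade(hi) > flesch_kincaid_grade(lo)

    def test_fog_zero_complex_is_mean_sentence_length_scaled(self):
        rng = random.Random(11)
        for _ in range(20):
            w = rng.randint(2, 300)
            s = rng.randint(1, w)
            assert gunning_fog(make_counts(w, s, w)) == pytest.approx(0.4 * w / s)

    def test_oracle_suite_fifty_random_tuples(self):
        """All count-based formulas agree with independently coded evaluations."""
        rng = random.Random(12345)
        for _ in range(50):
            w = rng.randint(1, 500)
            s = rng.randint(1, max(1, w // 2) if w > 1 else 1)
            syl = rng.randint(w, 4 * w)
            letters = rng.randint(w, 8 * w)
            chars = letters + rng.randint(0, w)
            cx = rng.randint(0, w)
            diff = rng.randint(0, w)
            c = make_counts(w, s, syl, letters=letters, chars=chars,
                            complex_words=cx, difficult=diff)
            assert flesch_reading_ease(c)[0] == pytest.approx(
                206.835 - 1.015 * (w / s) - 84.6 * (syl / w), abs=1e-9)
            assert flesch_kincaid_grade(c) == pytest.approx(
                0.39 * (w / s) + 11.8 * (syl / w) - 15.59, abs=1e-9)
            assert gunning_fog(c) == pytest.approx(
                0.4 * ((w / s) + 100 * cx / w), abs=1e-9)
            assert coleman_liau(c) == pytest.approx(
                0.0588 * (letters / w * 100) - 0.296 * (s / w * 100) - 15.8, abs=1e-9)
            assert automated_readability_index(c) == pytest.approx(
                4.71 * (chars / w) + 0.5 * (w / s), abs=1e-9)
            assert smog(c) == pytest.approx(
                1.0430 * math.sqrt(cx * 30 / s) + 3.1291, abs=1e-9)
            raw, adj = dale_chall(c)
            exp_raw = 0.1579 * (diff / w * 100) + 0.0496 * (w / s)
            assert raw == pytest.approx(exp_raw, abs=1e-9)
            assert adj == pytest.approx(
                exp_raw + (3.6365 if diff / w > 0.05 else 0.0), abs=1e-9)
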