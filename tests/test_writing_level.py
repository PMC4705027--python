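"""Modified Flesch-Kincaid writing level: cleaning, counting, grading."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthdemog import (
    clean_post_text,
    count_syllables,
    fk_grade,
    grade_to_bracket,
    split_sentences,
    user_writing_level,
)
from healthdemog.corpus import Post, UserRecord
from healthdemog.synthetic import WORD_BANKS, constant_grade_text
from healthdemog.writing_level import text_writing_level


class TestCleanPostText:
    def test_links_hashtags_and_mentions_removed(self):
        assert clean_post_text("read this http://x.co #hcsm now") == "read this now"
        assert clean_post_text("hey @doc www.example.org call") == "hey call"

    def test_plain_text_unchanged(self):
        assert clean_post_text("a plain sentence.") == "a plain sentence."

    def test_all_noise_collapses_to_empty(self):
        assert clean_post_text("#a #b #c") == ""


class TestSplitSentences:
    def test_terminal_punctuation_splits(self):
        assert split_sentences("I ran. You walked!") == [["I", "ran"], ["You", "walked"]]

    def test_trailing_text_is_a_sentence(self):
        assert split_sentences("no terminal punctuation") == [["no", "terminal", "punctuation"]]

    def test_naive_rule_splits_at_abbreviations(self):
        # documented limitation of the punctuation-only rule
        assert split_sentences("Dr. Smith left.") == [["Dr"], ["Smith", "left"]]

    def test_newline_runs_are_boundaries(self):
        assert split_sentences("first post\n\nsecond post") == [
            ["first", "post"],
            ["second", "post"],
        ]


class TestCountSyllables:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("cat", 1),
            ("beautiful", 3),  # eau | i | u vowel groups
            ("the", 1),  # silent-e rule floors at 1
            ("table", 2),  # consonant-le keeps its final group
            ("stone", 1),  # terminal silent e subtracted
            ("rhythm", 1),  # y as the only vowel group
            ("42", 1),  # no letters -> 1
        ],
    )
    def test_heuristic_pinned_values(self, word, expected):
        assert count_syllables(word) == expected

    def test_word_banks_agree_with_counter(self):
        for syllables, words in WORD_BANKS.items():
            for word in words:
                assert count_syllables(word) == syllables, word


class TestFkGrade:
    def test_hand_evaluations_of_printed_formula(self):
        assert fk_grade(10, 1) == pytest.approx(0.11, abs=1e-12)
        assert fk_grade(10.82, 1.5) == pytest.approx(6.3298, abs=1e-12)
        assert fk_grade(1, 1) == pytest.approx(-3.4, abs=1e-12)

    def test_non_positive_asl_rejected(self):
        with pytest.raises(ValueError):
            fk_grade(0, 1)

    def test_strictly_monotone_in_both_arguments(self):
        grades = [fk_grade(asl, 1.3) for asl in range(1, 101)]
        assert all(b > a for a, b in zip(grades, grades[1:]))
        grades = [fk_grade(12, 1 + k * 0.03) for k in range(100)]
        assert all(b > a for a, b in zip(grades, grades[1:]))


class TestGradeToBracket:
    @pytest.mark.parametrize(
        "grade,bracket",
        [(0.11, "0-5"), (5.5, "0-5"), (5.51, "6-9"), (9.5, "6-9"), (14.2, "10-16"), (-2.0, "0-5"), (18.0, "10-16")],
    )
    def test_cut_points_and_clamping(self, grade, bracket):
        assert grade_to_bracket(grade) == bracket


def _user_with_sentences(n, words=10, syllables=1):
    return UserRecord(user_id="u", posts=[Post(constant_grade_text(n, words, syllables, seed_or_rng=1))])


class TestUserWritingLevel:
    def test_under_100_words_excluded(self):
        stats = user_writing_level(_user_with_sentences(9, words=11))  # 99 words
        assert stats.bracket is None and stats.grade is None
        assert stats.word_count == 99

    def test_identical_sentences_yield_exact_asl_and_asw(self):
        stats = user_writing_level(_user_with_sentences(12, words=10, syllables=2))
        assert stats.asl == pytest.approx(10.0)
        assert stats.asw == pytest.approx(2.0)
        assert stats.grade == pytest.approx(fk_grade(10, 2))

    def test_long_sentences_omitted_without_changing_grade(self):
        base = _user_with_sentences(12, words=10)
        long_sentence = " ".join(["cat"] * 35) + "."
        with_long = UserRecord(user_id="u", posts=base.posts + [Post(long_sentence)])
        assert user_writing_level(with_long).grade == pytest.approx(user_writing_level(base).grade)

    def test_exactly_30_word_sentences_are_retained(self):
        user = _user_with_sentences(4, words=30)
        stats = user_writing_level(user)
        assert stats.sentence_count == 4 and stats.word_count == 120

    def test_description_counts_toward_total(self):
        text = constant_grade_text(6, 10, 1, seed_or_rng=2)
        user = UserRecord(user_id="u", posts=[Post(text)], description=text)
        assert user_writing_level(user).bracket is not None

    def test_posts_do_not_run_into_each_other(self):
        # two 5-word posts must be two sentences, not one 10-word sentence
        stats = text_writing_level(["one two three four five", "six seven eight nine ten"], min_words=1)
        assert stats.sentence_count == 2


@given(target=st.floats(0.5, 16.0), seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None)
def test_generated_text_hits_target_grade(target, seed):
    """Round trip: synthesized text measures within +-0.5 of its target."""
    from healthdemog import generate_text_with_target_grade

    text = generate_text_with_target_grade(target, 14, seed)
    stats = text_writing_level([text])
    assert stats.bracket is not None
    assert abs(stats.grade - target) <= 0.5
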