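"""Per-user writing level via a modified Flesch-Kincaid procedure.

The Flesch-Kincaid grade,

    grade = 0.39 * ASL + 11.8 * ASW - 15.59,

is computed over the concatenation of all of a user's posts and profile
description, with two modifications designed for social-media text:
sentences longer than 30 words are omitted (run-on, unpunctuated posts
otherwise inflate ASL), and users with fewer than 100 retained words are
excluded entirely.  Links, hashtags and @-mentions are stripped before
counting.  Grades bin into three brackets (0-5, 6-9, 10-16).

The syllable counter is a deterministic heuristic (maximal vowel groups
with a terminal silent-e rule) and is pluggable: any callable
``word -> int`` can replace it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional

FK_ASL_COEF = 0.39
FK_ASW_COEF = 11.8
FK_INTERCEPT = -15.59

DEFAULT_MIN_WORDS = 100
DEFAULT_MAX_SENTENCE_WORDS = 30

BRACKETS = ("0-5", "6-9", "10-16")

_NOISE_TOKEN_RE = re.compile(r"^(https?://\S*|www\.\S*|#\S+|@\S+)$", re.IGNORECASE)
_SENTENCE_SPLIT_RE = re.compile(r"[.!?]+|\n+")
_HAS_ALNUM_RE = re.compile(r"[A-Za-z0-9]")
_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")


def clean_post_text(text: str) -> str:
    """Strip URL, hashtag and @-mention tokens; normalize spaces.

    Newlines survive (they mark sentence boundaries downstream); runs of
    spaces and tabs collapse to single spaces.
    """
    lines = []
    for line in text.split("\n"):
        kept = [tok for tok in line.split() if not _NOISE_TOKEN_RE.match(tok)]
        lines.append(" ".join(kept))
    return "\n".join(lines).strip()


def split_sentences(text: str) -> List[List[str]]:
    """Split cleaned text into sentences of word tokens.

    Sentences end at runs of ``. ! ?`` or newlines; words are whitespace
    tokens containing at least one letter or digit.  Empty sentences are
    dropped; trailing text without terminal punctuation still counts as
    a sentence.  The rule is deliberately naive — "Dr. Smith left." is
    two sentences — because the grade formula assumes conventionally
    punctuated prose anyway.
    """
    sentences = []
    for raw in _SENTENCE_SPLIT_RE.split(text):
        words = [tok for tok in raw.split() if _HAS_ALNUM_RE.search(tok)]
        if words:
            sentences.append(words)
    return sentences


def count_syllables(word: str) -> int:
    """Heuristic syllable count, always >= 1.

    Count maximal vowel groups (a e i o u y) in the lowercased
    alphabetic residue; subtract one for a terminal silent "e" standing
    as its own group, unless it ends a consonant+"le" cluster ("table").
    Words with no letters count 1.
    """
    letters = "".join(c for c in word.lower() if "a" <= c <= "z")
    if not letters:
        return 1
    groups = _VOWEL_GROUP_RE.findall(letters)
    n = len(groups)
    if n > 1 and letters.endswith("e") and groups[-1] == "e":
        if not (
            letters.endswith("le")
            and len(letters) >= 3
            and letters[-3] not in "aeiouy"
        ):
            n -= 1
    return max(n, 1)


def fk_grade(asl: float, asw: float) -> float:
    """Flesch-Kincaid grade 0.39*ASL + 11.8*ASW - 15.59 (may be negative)."""
    if asl <= 0:
        raise ValueError("ASL must be positive")
    return FK_ASL_COEF * asl + FK_ASW_COEF * asw + FK_INTERCEPT


def grade_to_bracket(grade: float) -> str:
    """Bin a grade: <=5.5 -> 0-5; (5.5, 9.5] -> 6-9; >9.5 -> 10-16.

    Out-of-range grades clamp into the end brackets.
    """
    if grade <= 5.5:
        return "0-5"
    if grade <= 9.5:
        return "6-9"
    return "10-16"


@dataclass(frozen=True)
class WritingLevelStats:
    asl: float
    asw: float
    grade: Optional[float]
    word_count: int
    sentence_count: int
    bracket: Optional[str]  # None <=> user excluded (too few words)


EXCLUDED = WritingLevelStats(0.0, 0.0, None, 0, 0, None)


def text_writing_level(
    pieces: Iterable[str],
    min_words: int = DEFAULT_MIN_WORDS,
    max_sentence_words: int = DEFAULT_MAX_SENTENCE_WORDS,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> WritingLevelStats:
    """Grade a collection of text pieces (posts, description).

    Pieces are joined with newline boundaries so one post never runs
    into the next, cleaned, sentence-split, and sentences over
    ``max_sentence_words`` words are discarded.  Fewer than
    ``min_words`` retained words excludes the text (bracket None).
    """
    text = clean_post_text("\n".join(p for p in pieces if p))
    sentences = [s for s in split_sentences(text) if len(s) <= max_sentence_words]
    word_count = sum(len(s) for s in sentences)
    if word_count < min_words or not sentences:
        return WritingLevelStats(0.0, 0.0, None, word_count, len(sentences), None)
    syllables = sum(syllable_counter(w) for s in sentences for w in s)
    asl = word_count / len(sentences)
    asw = syllables / word_count
    grade = fk_grade(asl, asw)
    return WritingLevelStats(asl, asw, grade, word_count, len(sentences), grade_to_bracket(grade))


def user_writing_level(
    user,
    min_words: int = DEFAULT_MIN_WORDS,
    max_sentence_words: int = DEFAULT_MAX_SENTENCE_WORDS,
    syllable_counter: Callable[[str], int] = count_syllables,
) -> WritingLevelStats:
    """Writing level over all of a user's posts plus profile description."""
    pieces = [p.text for p in user.posts]
    if user.description:
        pieces.append(user.description)
    return text_writing_level(
        pieces,
        min_words=min_words,
        max_sentence_words=max_sentence_words,
        syllable_counter=syllable_counter,
    )
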