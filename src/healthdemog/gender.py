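"""First-name gender inference with reported > display-name > screen-name
precedence.

Where a source reports gender, that value wins.  Otherwise the display
name is searched against the filtered SSA first-name table, and failing
that a first name is extracted from the screen name by segmenting at
separators, digit boundaries and camel-case boundaries.  Every call
carries provenance so downstream tables can distinguish reported from
classified attributes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from ._util import clean_name
from .reference_tables import GenderNameTable

TOKEN = "token"
SUBSTRING = "substring"


@dataclass(frozen=True)
class GenderCall:
    label: str  # "male" | "female" | "unknown"
    provenance: str  # "reported" | "first_name" | "screen_name" | "none"
    matched_name: Optional[str] = None
    probability: Optional[float] = None


UNKNOWN = GenderCall("unknown", "none")

_WORD_SPLIT_RE = re.compile(r"[^A-Za-z]+")
# camel-case aware segmenter: "MaryJane1988" -> Mary, Jane, 1988
_SEGMENT_RE = re.compile(r"[A-Z]+(?![a-z])|[A-Z][a-z]*|[a-z]+|\d+")


def classify_gender_from_display_name(
    display_name: str, table: GenderNameTable, mode: str = TOKEN
) -> GenderCall:
    """Look a display name up in the gender table.

    token mode (default): the display name is split on whitespace and
    punctuation, each token cleaned, and the first token found in the
    table decides the call.

    substring mode: any table name occurring as a substring of the
    cleaned, concatenated display name matches, preferring the longest
    (then alphabetically first) name.  This mirrors literal
    "name contained in the user-specified name" matching at the cost of
    false positives ("ann" inside "hannah"), which is why it is not the
    default.
    """
    if not display_name:
        return UNKNOWN
    if mode == TOKEN:
        for token in _WORD_SPLIT_RE.split(display_name):
            cleaned = clean_name(token)
            if cleaned and cleaned in table:
                e = table.get(cleaned)
                return GenderCall(e.gender, "first_name", cleaned, e.probability)
        return UNKNOWN
    if mode == SUBSTRING:
        haystack = clean_name(display_name)
        if not haystack:
            return UNKNOWN
        best = None
        for name in table.entries:
            if name in haystack:
                key = (-len(name), name)
                if best is None or key < best[0]:
                    best = (key, name)
        if best is not None:
            name = best[1]
            e = table.get(name)
            return GenderCall(e.gender, "first_name", name, e.probability)
        return UNKNOWN
    raise ValueError(f"unknown match mode {mode!r}")


def _segments(screen_name: str) -> list:
    """Split a screen name into candidate name segments.

    Separators (``_ . -``), digit runs and lower-to-upper camel-case
    boundaries all end a segment; segments are cleaned to lowercase
    alphabetic strings, empties dropped, order preserved.
    """
    segments = []
    for chunk in re.split(r"[._\-\s]+", screen_name):
        for seg in _SEGMENT_RE.findall(chunk):
            cleaned = clean_name(seg)
            if cleaned:
                segments.append(cleaned)
    return segments


_MIN_PREFIX = 2  # single letters never count as an embedded name


def extract_first_name_from_screen_name(
    screen_name: str, table: GenderNameTable
) -> Optional[str]:
    """Find a table first name embedded in a screen name.

    Pass 1: a segment that is exactly a table name, earliest segment
    wins.  Pass 2: the longest table name that is a prefix (>= 2 chars)
    of a segment, again preferring earlier segments.
    """
    if not screen_name:
        return None
    segments = _segments(screen_name)
    for seg in segments:
        if seg in table:
            return seg
    for seg in segments:
        for length in range(len(seg) - 1, _MIN_PREFIX - 1, -1):
            prefix = seg[:length]
            if prefix in table:
                return prefix
    return None


def resolve_gender(user, table: GenderNameTable, mode: str = TOKEN) -> GenderCall:
    """Resolve a user's gender: reported field, else display name, else
    screen name; unknown when every stage fails."""
    if user.reported_gender in ("male", "female"):
        return GenderCall(user.reported_gender, "reported")
    if user.display_name:
        call = classify_gender_from_display_name(user.display_name, table, mode=mode)
        if call.label != "unknown":
            return call
    if user.screen_name:
        matched = extract_first_name_from_screen_name(user.screen_name, table)
        if matched is not None:
            e = table.get(matched)
            return GenderCall(e.gender, "screen_name", matched, e.probability)
    return UNKNOWN
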