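"""Surname-based ethnicity classification.

The last whitespace token of the display name is treated as the surname
and looked up exactly in the filtered census surname table; the table's
majority ethnicity becomes the call.  Screen names are never used —
screen-name-derived surnames are too noisy to classify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._util import clean_name
from .reference_tables import SurnameEthnicityTable


@dataclass(frozen=True)
class EthnicityCall:
    label: str  # "white" | "black" | "asian" | "hispanic" | "unknown"
    matched_surname: Optional[str] = None
    probability: Optional[float] = None


UNKNOWN = EthnicityCall("unknown")


def extract_last_name(display_name: str) -> Optional[str]:
    """Cleaned last whitespace token; None for empty or single-token names.

    Compound surnames resolve to their final token ("de la Cruz" ->
    "cruz"), matching the census file's single-token surname keys.
    """
    if not display_name:
        return None
    tokens = display_name.split()
    if len(tokens) < 2:
        return None
    cleaned = clean_name(tokens[-1])
    return cleaned or None


def classify_ethnicity(user, table: SurnameEthnicityTable) -> EthnicityCall:
    """Classify a user's ethnicity from the display-name surname."""
    if not user.display_name:
        return UNKNOWN
    surname = extract_last_name(user.display_name)
    if surname is None:
        return UNKNOWN
    entry = table.get(surname)
    if entry is None:
        return UNKNOWN
    return EthnicityCall(entry.ethnicity, surname, entry.probability)
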