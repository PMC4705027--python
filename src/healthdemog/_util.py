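"""Shared helpers: name cleaning, parse bookkeeping, error types."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Generic, TypeVar

T = TypeVar("T")


class FormatError(ValueError):
    """An input stream is unreadable as the expected dialect."""


class ConfigurationError(ValueError):
    """A required configuration object is missing or empty."""


def clean_name(raw: str) -> str:
    """Lowercase a name and strip every non-alphabetic character.

    The same transform is applied when building the lookup tables and when
    classifying, so "J0hn-Paul" and "j.ohnpaul" collide on purpose.  Only
    ASCII letters survive; the result may be empty.
    """
    return "".join(c for c in raw.lower() if "a" <= c <= "z")


@dataclass
class ParseResult(Generic[T]):
    """Records parsed from a stream plus the count of skipped bad rows."""

    records: list[T] = field(default_factory=list)
    skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)
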