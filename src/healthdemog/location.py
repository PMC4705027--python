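"""Location-string normalization, frequency filtering, offline
geocoding, and per-capita state participation rates.

Free-text locations ("NY, NY") are lowercased and stripped of
non-alphanumerics, rare strings (frequency < 14 by default) are dropped,
and survivors are resolved through an exact-match offline gazetteer.
Non-US resolutions are retained but excluded from state-level analyses.
Sources that report a state directly bypass all of this.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Union

from ._util import ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_LOCATION_FREQUENCY = 14

_NON_ALNUM_RE = re.compile(r"[^a-z0-9 ]+")
_SPACE_RUN_RE = re.compile(r" +")


@dataclass(frozen=True)
class ResolvedLocation:
    city: Optional[str]
    state: Optional[str]  # 2-letter code for US locations
    country: str  # ISO-ish country code, "US" for domestic
    source_string: str = ""

    @property
    def is_us(self) -> bool:
        return self.country == "US"


def normalize_location_string(raw: str) -> str:
    """Lowercase, drop non-alphanumerics, collapse spaces, trim."""
    lowered = raw.lower()
    stripped = _NON_ALNUM_RE.sub("", lowered)
    return _SPACE_RUN_RE.sub(" ", stripped).strip()


def filter_by_frequency(
    strings: Union[Counter, Iterable[str]],
    min_frequency: int = DEFAULT_MIN_LOCATION_FREQUENCY,
) -> Counter:
    """Keep strings whose corpus frequency is >= ``min_frequency``.

    Frequency 14 survives the default cut; 13 does not.
    """
    counts = strings if isinstance(strings, Counter) else Counter(strings)
    return Counter({s: n for s, n in counts.items() if n >= min_frequency})


def load_gazetteer(path: Union[str, Path]) -> Dict[str, ResolvedLocation]:
    """Load the exact-match gazetteer CSV (normalized,city,state,country)."""
    gazetteer: Dict[str, ResolvedLocation] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            key = normalize_location_string(row["normalized"])
            gazetteer[key] = ResolvedLocation(
                city=row.get("city") or None,
                state=(row.get("state") or None),
                country=row["country"],
                source_string=key,
            )
    if not gazetteer:
        raise ConfigurationError(f"gazetteer {path} is empty")
    return gazetteer


def load_populations(path: Union[str, Path]) -> Dict[str, int]:
    """Load the state-population CSV (``state,population``)."""
    populations: Dict[str, int] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            populations[row["state"]] = int(row["population"])
    if not populations:
        raise ConfigurationError(f"population file {path} is empty")
    return populations


def geocode(
    normalized: str, gazetteer: Mapping[str, ResolvedLocation]
) -> Optional[ResolvedLocation]:
    """Exact lookup of a normalized string; None on miss."""
    if not gazetteer:
        raise ConfigurationError("gazetteer is empty")
    return gazetteer.get(normalized)


@dataclass(frozen=True)
class StateCount:
    user_count: float
    population: int
    rate: float  # user_count / population


@dataclass
class StateParticipation:
    """Per-capita participation per state; zero-user states included."""

    states: Dict[str, StateCount] = field(default_factory=dict)
    excluded: int = 0  # users in states missing from the population map

    def rates(self) -> Dict[str, float]:
        return {s: c.rate for s, c in self.states.items()}

    def total_users(self) -> float:
        return sum(c.user_count for c in self.states.values())


def per_capita_by_state(
    users: Iterable, populations: Mapping[str, int]
) -> StateParticipation:
    """Count users per resolved US state and normalize by population.

    ``users`` may be state-code strings or objects with a ``state``
    attribute (None entries skipped).  Users in states absent from the
    population map are logged and excluded; every state in the map
    appears in the result, at rate 0 when it has no users.
    """
    for state, pop in populations.items():
        if pop <= 0:
            raise ValueError(f"population for {state} must be positive")
    counts: Counter = Counter()
    excluded = 0
    for u in users:
        state = u if isinstance(u, str) or u is None else getattr(u, "state", None)
        if state is None:
            continue
        if state not in populations:
            logger.warning("user in state %r absent from population map; excluded", state)
            excluded += 1
            continue
        counts[state] += 1
    participation = StateParticipation(excluded=excluded)
    for state, pop in populations.items():
        n = float(counts.get(state, 0))
        participation.states[state] = StateCount(n, pop, n / pop)
    return participation
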