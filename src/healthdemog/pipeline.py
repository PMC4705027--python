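"""End-to-end profiling: corpus users -> per-user demographic profiles.

Ties the classifiers together with the standard precedence rules:
reported attributes always win over classified ones, location strings
are frequency-filtered per source before geocoding, and every inferred
attribute keeps its provenance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

from . import age as _age
from . import ethnicity as _ethnicity
from . import gender as _gender
from . import location as _location
from . import writing_level as _writing
from .reference_tables import GenderNameTable, SurnameEthnicityTable


@dataclass
class DemographicProfile:
    user_id: str
    source: str
    gender: _gender.GenderCall
    ethnicity: _ethnicity.EthnicityCall
    age: _age.AgeReport
    writing: Optional[_writing.WritingLevelStats]
    location: Optional[_location.ResolvedLocation]
    state: Optional[str]  # US state code; None when unresolved or non-US
    state_provenance: str  # "reported" | "geocoded" | "none"


def profiles_to_frame(profiles: Iterable[DemographicProfile]):
    """Flatten profiles to a DataFrame (one row per user) for CSV export."""
    import pandas as pd

    rows = []
    for p in profiles:
        rows.append(
            {
                "user_id": p.user_id,
                "source": p.source,
                "gender": p.gender.label,
                "gender_provenance": p.gender.provenance,
                "ethnicity": p.ethnicity.label,
                "age_kind": p.age.kind,
                "age_value": p.age.value,
                "age_low": p.age.low,
                "age_high": p.age.high,
                "writing_grade": p.writing.grade if p.writing else None,
                "writing_bracket": p.writing.bracket if p.writing else None,
                "state": p.state,
                "state_provenance": p.state_provenance,
            }
        )
    return pd.DataFrame(rows)


def profiles_from_frame(frame) -> List[DemographicProfile]:
    """Rebuild lightweight profiles from :func:`profiles_to_frame` output."""

    def _na(v):
        return None if v is None or (isinstance(v, float) and v != v) else v

    profiles = []
    for row in frame.to_dict("records"):
        kind = row["age_kind"]
        if kind == "exact":
            age = _age.AgeReport.exact(int(row["age_value"]))
        elif kind == "range":
            age = _age.AgeReport.range_(int(row["age_low"]), int(row["age_high"]))
        else:
            age = _age.MISSING
        grade = _na(row["writing_grade"])
        bracket = _na(row["writing_bracket"])
        writing = (
            _writing.WritingLevelStats(0.0, 0.0, grade, 0, 0, bracket)
            if (grade is not None or bracket is not None)
            else None
        )
        profiles.append(
            DemographicProfile(
                user_id=row["user_id"],
                source=row["source"],
                gender=_gender.GenderCall(row["gender"], row["gender_provenance"]),
                ethnicity=_ethnicity.EthnicityCall(row["ethnicity"]),
                age=age,
                writing=writing,
                location=None,
                state=_na(row["state"]),
                state_provenance=row["state_provenance"],
            )
        )
    return profiles


def profile_corpus(
    users: Iterable,
    gender_table: GenderNameTable,
    ethnicity_table: SurnameEthnicityTable,
    gazetteer: Optional[Mapping[str, _location.ResolvedLocation]] = None,
    gender_mode: str = _gender.TOKEN,
    min_words: int = _writing.DEFAULT_MIN_WORDS,
    max_sentence_words: int = _writing.DEFAULT_MAX_SENTENCE_WORDS,
    min_location_frequency: int = _location.DEFAULT_MIN_LOCATION_FREQUENCY,
    compute_writing: bool = True,
) -> List[DemographicProfile]:
    """Profile every user in a corpus.

    Location handling follows the per-source convention: normalized
    location strings are counted within each source, strings rarer than
    ``min_location_frequency`` are dropped, and survivors are geocoded
    through the offline gazetteer.  Users with a pre-resolved
    ``reported_state`` bypass that path entirely.
    """
    users = list(users)

    freq_by_source: Dict[str, Counter] = {}
    for u in users:
        if u.location_string and not u.reported_state:
            freq_by_source.setdefault(u.source, Counter())[
                _location.normalize_location_string(u.location_string)
            ] += 1
    retained_by_source = {
        src: _location.filter_by_frequency(counts, min_location_frequency)
        for src, counts in freq_by_source.items()
    }

    profiles: List[DemographicProfile] = []
    for u in users:
        resolved = None
        state = None
        state_prov = "none"
        if u.reported_state:
            state = u.reported_state
            state_prov = "reported"
        elif u.location_string and gazetteer is not None:
            normalized = _location.normalize_location_string(u.location_string)
            if normalized in retained_by_source.get(u.source, ()):
                resolved = _location.geocode(normalized, gazetteer)
                if resolved is not None and resolved.is_us and resolved.state:
                    state = resolved.state
                    state_prov = "geocoded"

        profiles.append(
            DemographicProfile(
                user_id=u.user_id,
                source=u.source,
                gender=_gender.resolve_gender(u, gender_table, mode=gender_mode),
                ethnicity=_ethnicity.classify_ethnicity(u, ethnicity_table),
                age=u.reported_age if u.reported_age is not None else _age.MISSING,
                writing=(
                    _writing.user_writing_level(
                        u, min_words=min_words, max_sentence_words=max_sentence_words
                    )
                    if compute_writing
                    else None
                ),
                location=resolved,
                state=state,
                state_provenance=state_prov,
            )
        )
    return profiles
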