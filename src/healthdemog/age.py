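"""Age parsing, uniform range redistribution, and census-bracket binning.

Some sources report an exact age, one reports an inclusive range
(e.g. "35-45").  Range-reported users are spread uniformly over the
years of the range as fractional user-equivalents, then all mass is
binned into the census brackets 0-17, 18-34, 35-44, 45-64, 65+.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple, Union

AGE_MIN, AGE_MAX = 0, 120

#: census bracket label -> (low, high) inclusive years
BRACKETS: Tuple[Tuple[str, int, int], ...] = (
    ("0-17", 0, 17),
    ("18-34", 18, 34),
    ("35-44", 35, 44),
    ("45-64", 45, 64),
    ("65+", 65, AGE_MAX),
)
BRACKET_LABELS = tuple(b[0] for b in BRACKETS)


@dataclass(frozen=True)
class AgeReport:
    kind: str  # "exact" | "range" | "missing"
    value: Optional[int] = None
    low: Optional[int] = None
    high: Optional[int] = None

    @classmethod
    def exact(cls, value: int) -> "AgeReport":
        return cls("exact", value=value)

    @classmethod
    def range_(cls, low: int, high: int) -> "AgeReport":
        return cls("range", low=low, high=high)

    @classmethod
    def missing(cls) -> "AgeReport":
        return cls("missing")


MISSING = AgeReport.missing()

_RANGE_RE = re.compile(r"^\s*(\d{1,3})\s*[-–]\s*(\d{1,3})\s*$")
_EXACT_RE = re.compile(r"^\s*(\d{1,3})\s*$")


def parse_age(raw: str) -> AgeReport:
    """Parse "37" to exact, "35-45" to an inclusive range; else missing.

    Out-of-range values ([0, 120]) and inverted ranges are missing — the
    sink state, never an error.
    """
    if raw is None:
        return MISSING
    m = _EXACT_RE.match(raw)
    if m:
        v = int(m.group(1))
        return AgeReport.exact(v) if AGE_MIN <= v <= AGE_MAX else MISSING
    m = _RANGE_RE.match(raw)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if AGE_MIN <= lo <= hi <= AGE_MAX:
            return AgeReport.range_(lo, hi)
    return MISSING


def coerce_age(value: Union[int, str, list, tuple, AgeReport, None]) -> AgeReport:
    """Coerce a JSON-ish age value (int, "35-45", [35, 45]) to an AgeReport."""
    if value is None:
        return MISSING
    if isinstance(value, AgeReport):
        return value
    if isinstance(value, bool):
        return MISSING
    if isinstance(value, int):
        return AgeReport.exact(value) if AGE_MIN <= value <= AGE_MAX else MISSING
    if isinstance(value, (list, tuple)) and len(value) == 2:
        try:
            lo, hi = int(value[0]), int(value[1])
        except (TypeError, ValueError):
            return MISSING
        if AGE_MIN <= lo <= hi <= AGE_MAX:
            return AgeReport.range_(lo, hi)
        return MISSING
    if isinstance(value, str):
        return parse_age(value)
    return MISSING


def distribute_age_range(report: AgeReport, weight: float = 1.0) -> dict:
    """Spread *weight* uniformly over each year of an inclusive range.

    A range (35, 45) spans 11 years, so each year receives weight/11.
    """
    if report.kind != "range":
        raise ValueError(f"distribute_age_range requires a range report, got {report.kind}")
    n_years = report.high - report.low + 1
    per_year = weight / n_years
    return {year: per_year for year in range(report.low, report.high + 1)}


def bracket_of(age: int) -> str:
    """Census bracket label for an exact age."""
    for label, lo, hi in BRACKETS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")


@dataclass
class AgeGroupDistribution:
    """User-equivalent mass per census bracket."""

    weights: dict = field(default_factory=lambda: {label: 0.0 for label in BRACKET_LABELS})
    total: float = 0.0

    def percentages(self) -> dict:
        if self.total == 0:
            return {label: 0.0 for label in BRACKET_LABELS}
        return {label: 100.0 * w / self.total for label, w in self.weights.items()}


def bin_ages(reports: Iterable) -> AgeGroupDistribution:
    """Bin (AgeReport, weight) pairs — or bare AgeReports at weight 1 —
    into the census brackets.

    Exact reports contribute their whole weight to one bracket; range
    reports contribute per-year masses; missing reports are excluded
    from the total.
    """
    dist = AgeGroupDistribution()
    for item in reports:
        if isinstance(item, AgeReport):
            report, weight = item, 1.0
        else:
            report, weight = item
        if report.kind == "missing":
            continue
        if report.kind == "exact":
            dist.weights[bracket_of(report.value)] += weight
        else:
            for year, mass in distribute_age_range(report, weight).items():
                dist.weights[bracket_of(year)] += mass
        dist.total += weight
    return dist


def expected_age(report: AgeReport) -> Optional[float]:
    """Point age for a report: the value, or the range midpoint; None if missing."""
    if report.kind == "exact":
        return float(report.value)
    if report.kind == "range":
        return (report.low + report.high) / 2.0
    return None
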