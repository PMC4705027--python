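"""Reference lookup tables for name-based demographic classification.

Two tables drive the classifiers:

* a first-name gender table aggregated from SSA-style yearly birth-name
  files (``yob<YYYY>.txt``, rows ``name,M|F,count``), filtered to names
  with aggregate frequency >= 10,000 and discriminative gender
  probability >= 95%;
* a surname ethnicity table from a census-2000-style surname file
  (columns ``name,count,pctwhite,pctblack,pctapi,pcthispanic``), filtered
  to surnames with frequency >= 1000 and a majority-ethnicity share
  >= 80%.

Both tables key on cleaned (lowercase, alphabetic-only) names and carry
the build parameters so serialized tables are self-describing.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from ._util import FormatError, ParseResult, clean_name

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
ETHNICITIES = ("white", "black", "asian", "hispanic")

_SSA_GENDER = {"M": MALE, "F": FEMALE}
_Source = Union[str, Path, IO[str]]


def _open(source: _Source):
    """Return (file-object, needs_close) for a path or stream."""
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class YearlyNameRecord:
    name: str
    gender: str  # "male" | "female"
    count: int
    year: int


@dataclass(frozen=True)
class SurnameDistributionRecord:
    surname: str
    total_frequency: int
    shares: dict  # ethnicity -> fraction in [0, 1]


# ---------------------------------------------------------------------------
# tables


@dataclass(frozen=True)
class GenderEntry:
    gender: str
    probability: float
    total_frequency: int


@dataclass(frozen=True)
class EthnicityEntry:
    ethnicity: str
    probability: float
    total_frequency: int


@dataclass
class GenderNameTable:
    """Cleaned first name -> (gender, probability, aggregate frequency)."""

    entries: dict = field(default_factory=dict)
    build_params: dict = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str):
        return self.entries.get(name)

    def to_tsv(self, path: Union[str, Path]) -> None:
        _table_to_tsv(path, self.entries, self.build_params, "gender")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "GenderNameTable":
        entries, params = _table_from_tsv(path, GenderEntry)
        return cls(entries=entries, build_params=params)


@dataclass
class SurnameEthnicityTable:
    """Cleaned surname -> (majority ethnicity, probability, frequency)."""

    entries: dict = field(default_factory=dict)
    build_params: dict = field(default_factory=dict)

    def __contains__(self, surname: str) -> bool:
        return surname in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, surname: str):
        return self.entries.get(surname)

    def to_tsv(self, path: Union[str, Path]) -> None:
        _table_to_tsv(path, self.entries, self.build_params, "ethnicity")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SurnameEthnicityTable":
        entries, params = _table_from_tsv(path, EthnicityEntry)
        return cls(entries=entries, build_params=params)


_TSV_VERSION = 1


def _table_to_tsv(path, entries, build_params, label_field):
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# healthdemog table v{_TSV_VERSION}\n")
        fh.write(f"# build_params: {json.dumps(build_params, sort_keys=True)}\n")
        fh.write("name\tlabel\tprobability\tfrequency\n")
        for name in sorted(entries):
            e = entries[name]
            label = getattr(e, label_field)
            fh.write(f"{name}\t{label}\t{e.probability!r}\t{e.total_frequency}\n")


def _table_from_tsv(path, entry_cls):
    params: dict = {}
    entries: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# build_params:"):
                params = json.loads(line.split(":", 1)[1])
            elif line.startswith("#") or line.startswith("name\t") or not line:
                continue
            else:
                name, label, prob, freq = line.split("\t")
                entries[name] = entry_cls(label, float(prob), int(freq))
    return entries, params


# ---------------------------------------------------------------------------
# SSA yearly birth-name files


def read_ssa_year_file(source: _Source, year: int) -> ParseResult:
    """Parse one SSA-style yearly file (rows ``name,M|F,count``).

    Malformed rows are skipped with a warning and counted in the result;
    a stream with zero parseable rows raises :class:`FormatError`.
    """
    fh, needs_close = _open(source)
    result: ParseResult = ParseResult()
    try:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                name, gender_code, count_s = row[0], row[1].strip(), row[2]
                gender = _SSA_GENDER[gender_code.upper()]
                count = int(count_s)
                if count < 0:
                    raise ValueError("negative count")
                cleaned = clean_name(name)
                if not cleaned:
                    raise ValueError("empty name after cleaning")
            except (IndexError, KeyError, ValueError) as exc:
                logger.warning("skipping row %d (%r): %s", lineno, row, exc)
                result.skipped += 1
                continue
            result.records.append(YearlyNameRecord(cleaned, gender, count, year))
    except OSError as exc:
        raise IOError(f"cannot read SSA file: {exc}") from exc
    finally:
        if needs_close:
            fh.close()
    if not result.records:
        raise FormatError(f"no parseable rows in SSA file for year {year}")
    return result


_YOB_RE = re.compile(r"yob(\d{4})\.txt$")


def read_ssa_directory(
    directory: Union[str, Path], year_start: int = 1935, year_end: int = 1995
) -> list:
    """Read every ``yob<YYYY>.txt`` in *directory* with year in the span."""
    directory = Path(directory)
    records: list[YearlyNameRecord] = []
    found = False
    for path in sorted(directory.glob("yob*.txt")):
        m = _YOB_RE.search(path.name)
        if not m:
            continue
        year = int(m.group(1))
        if year_start <= year <= year_end:
            found = True
            records.extend(read_ssa_year_file(path, year).records)
    if not found:
        raise FormatError(
            f"no yob<YYYY>.txt files in {directory} for {year_start}-{year_end}"
        )
    return records


def build_gender_table(
    records: Iterable[YearlyNameRecord],
    min_frequency: int = 10_000,
    min_probability: float = 0.95,
    top_k_per_year: int | None = None,
) -> GenderNameTable:
    """Aggregate yearly records into the filtered gender lookup table.

    Per name, counts are summed over all years and genders; the
    discriminative probability is max(male, female) / total and the label
    is the argmax.  Entries failing either threshold are dropped
    (thresholds are keep-at-boundary: ``>=``).  Exact male/female ties
    are dropped as unclassifiable.

    ``top_k_per_year`` optionally restricts each (year, gender) slice to
    its k highest-count rows before aggregating, reproducing the
    "top 1000 names per year per gender" construction when fed full
    yearly files.
    """
    records = list(records)
    if top_k_per_year is not None:
        by_slice: dict = defaultdict(list)
        for r in records:
            by_slice[(r.year, r.gender)].append(r)
        kept: list[YearlyNameRecord] = []
        for slice_records in by_slice.values():
            slice_records.sort(key=lambda r: (-r.count, r.name))
            kept.extend(slice_records[:top_k_per_year])
        records = kept

    counts: dict = defaultdict(lambda: {MALE: 0, FEMALE: 0})
    for r in records:
        counts[r.name][r.gender] += r.count

    entries: dict = {}
    for name in sorted(counts):
        male, female = counts[name][MALE], counts[name][FEMALE]
        total = male + female
        if total < min_frequency or total == 0:
            continue
        if male == female:  # unclassifiable tie
            continue
        top, label = (male, MALE) if male > female else (female, FEMALE)
        probability = top / total
        if probability < min_probability:
            continue
        entries[name] = GenderEntry(label, probability, total)

    params = {
        "min_frequency": min_frequency,
        "min_probability": min_probability,
        "top_k_per_year": top_k_per_year,
    }
    return GenderNameTable(entries=entries, build_params=params)


# ---------------------------------------------------------------------------
# census surname files

_REQUIRED_CENSUS_COLS = ("name", "count", "pctwhite", "pctblack", "pctapi", "pcthispanic")
_PCT_COL = {"white": "pctwhite", "black": "pctblack", "asian": "pctapi", "hispanic": "pcthispanic"}


def read_census_surname_file(source: _Source) -> list:
    """Parse a census-style surname distribution file.

    Percent columns become fractions; suppressed cells ``(S)`` are read
    as zero with a logged note.  The census "other / two or more races"
    remainder is not stored, so shares need not sum to 1.
    """
    fh, needs_close = _open(source)
    try:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("census surname file is empty")
        fieldmap = {f.lower().strip(): f for f in reader.fieldnames}
        missing = [c for c in _REQUIRED_CENSUS_COLS if c not in fieldmap]
        if missing:
            raise FormatError(f"census surname file missing columns: {missing}")
        records: list[SurnameDistributionRecord] = []
        n_suppressed = 0
        for row in reader:
            surname = clean_name(row[fieldmap["name"]])
            if not surname:
                continue
            try:
                freq = int(float(row[fieldmap["count"]]))
            except ValueError:
                continue
            shares = {}
            for eth, col in _PCT_COL.items():
                cell = row[fieldmap[col]].strip()
                if cell in ("(S)", "S", ""):
                    n_suppressed += 1
                    shares[eth] = 0.0
                else:
                    shares[eth] = float(cell) / 100.0
            records.append(SurnameDistributionRecord(surname, freq, shares))
        if n_suppressed:
            logger.info("census file: %d suppressed '(S)' cells read as 0", n_suppressed)
        return records
    finally:
        if needs_close:
            fh.close()


def build_ethnicity_table(
    records: Iterable[SurnameDistributionRecord],
    min_frequency: int = 1000,
    min_majority_probability: float = 0.80,
) -> SurnameEthnicityTable:
    """Filter surname records into the majority-ethnicity lookup table.

    A surname is kept iff its frequency is >= ``min_frequency`` and the
    largest ethnicity share is >= ``min_majority_probability`` (both
    keep-at-boundary).  Exact ties for the largest share drop the record.
    """
    entries: dict = {}
    for r in records:
        if r.total_frequency < min_frequency or not r.shares:
            continue
        top = max(r.shares.values())
        if top < min_majority_probability:
            continue
        winners = [e for e, s in r.shares.items() if s == top]
        if len(winners) != 1:
            continue
        entries[r.surname] = EthnicityEntry(winners[0], top, r.total_frequency)

    params = {
        "min_frequency": min_frequency,
        "min_majority_probability": min_majority_probability,
    }
    return SurnameEthnicityTable(entries=entries, build_params=params)
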