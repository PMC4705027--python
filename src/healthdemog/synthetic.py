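"""Synthetic fixtures and corpora with known ground-truth demographics.

Nothing downloadable stands behind this package's analyses, so every
input the pipeline consumes can be generated here: SSA-style yearly
name files, a census-style surname distribution file, an offline
gazetteer with state populations and covariates, and JSONL user corpora
whose true gender / ethnicity / age / state / writing level are known
per user.

Design points that matter for testing:

* Categorical attributes are assigned by largest-remainder quota, not
  Bernoulli draws, so a corpus with gender mix 0.70 contains *exactly*
  70% women whenever 0.70 * n is whole — classifier recovery tests can
  then assert equality instead of confidence intervals.
* Post text is composed from closed word banks whose syllable counts
  the default counter reproduces exactly, so a target Flesch-Kincaid
  grade can be hit to within a known tolerance by construction.
* All randomness flows from a single seed through one generator; the
  same seed reproduces every byte of every file.

Default mixtures mirror the drug-review-style distributions this kind
of corpus exhibits (roughly 78% female, middle-aged, writing grades
concentrated in the 6-9 bracket), with social-network-style ethnicity
shares; any study condition can be overridden per CorpusSpec field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import age as _age
from . import writing_level as _writing
from .corpus import Post, UserRecord
from .location import ResolvedLocation

# ---------------------------------------------------------------------------
# word banks (syllable counts verified against writing_level.count_syllables)

WORD_BANKS: Dict[int, Tuple[str, ...]] = {
    1: ("cat", "dog", "sun", "map", "red", "fish", "hand", "tree", "milk",
        "green", "bed", "rock", "dust", "bird", "wind", "salt", "rain", "frost"),
    2: ("paper", "window", "doctor", "happy", "river", "garden", "winter",
        "signal", "master", "pattern", "morning", "yellow"),
    3: ("hospital", "banana", "digital", "memory", "officer", "capital",
        "general", "editor", "family", "holiday", "animal", "camera"),
    4: ("information", "television", "calculator", "category", "supervisor",
        "democracy", "operator", "experiment"),
}

_BANKS_CHECKED = False


def _check_banks() -> None:
    global _BANKS_CHECKED
    if _BANKS_CHECKED:
        return
    for syllables, words in WORD_BANKS.items():
        for word in words:
            got = _writing.count_syllables(word)
            if got != syllables:
                raise AssertionError(f"bank word {word!r}: counter says {got}, bank says {syllables}")
    _BANKS_CHECKED = True


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def constant_grade_text(
    n_sentences: int,
    words_per_sentence: int,
    syllables_per_word: int,
    seed_or_rng=0,
) -> str:
    """Text with exactly known ASL and ASW (one word bank throughout).

    With 10-word sentences of monosyllables the Flesch-Kincaid grade is
    exactly 0.39*10 + 11.8*1 - 15.59 = 0.11.
    """
    _check_banks()
    rng = _as_rng(seed_or_rng)
    bank = WORD_BANKS[syllables_per_word]
    sentences = []
    for _ in range(n_sentences):
        words = [bank[rng.integers(0, len(bank))] for _ in range(words_per_sentence)]
        sentences.append(" ".join(words).capitalize() + ".")
    return " ".join(sentences)


def generate_text_with_target_grade(
    target: float,
    n_sentences: int,
    seed_or_rng=0,
    words_per_sentence: Optional[int] = None,
) -> str:
    """Compose sentences whose expected Flesch-Kincaid grade is near *target*.

    Sentence length is fixed (10 words unless the target demands shorter
    sentences to keep ASW >= 1); per-word syllable counts are chosen
    greedily so the running mean tracks the ASW the grade formula
    requires.  The measured grade lands within +-0.5 of the target; with
    n_sentences >= 12 the text has >= 100 words, clearing the default
    inclusion threshold.
    """
    _check_banks()
    if not (-3.0 <= target <= 20.0):
        raise ValueError(f"target grade {target} outside [-3, 20]")
    if n_sentences < 1:
        raise ValueError("need at least one sentence")
    rng = _as_rng(seed_or_rng)

    wps = words_per_sentence
    if wps is None:
        wps = 10
        if (target - _writing.FK_INTERCEPT - _writing.FK_ASL_COEF * wps) / _writing.FK_ASW_COEF < 1.0:
            # monosyllabic floor: shorten sentences instead
            wps = max(2, round((target - _writing.FK_INTERCEPT - _writing.FK_ASW_COEF) / _writing.FK_ASL_COEF))
    asw_needed = (target - _writing.FK_INTERCEPT - _writing.FK_ASL_COEF * wps) / _writing.FK_ASW_COEF
    if asw_needed < 1.0 - 1e-9 or asw_needed > max(WORD_BANKS):
        raise ValueError(f"target {target} unreachable with {wps}-word sentences")
    asw_needed = max(asw_needed, 1.0)

    total_words = wps * n_sentences
    words: List[str] = []
    syllables_so_far = 0
    for k in range(total_words):
        desired = asw_needed * (k + 1)
        s = int(round(desired - syllables_so_far))
        s = min(max(s, 1), max(WORD_BANKS))
        bank = WORD_BANKS[s]
        words.append(bank[rng.integers(0, len(bank))])
        syllables_so_far += s

    sentences = [
        " ".join(words[i : i + wps]).capitalize() + "."
        for i in range(0, total_words, wps)
    ]
    return " ".join(sentences)


# ---------------------------------------------------------------------------
# reference fixture files

_FEMALE_NAMES = (
    "anna", "clara", "diana", "elena", "fiona", "grace", "helen", "irene",
    "julia", "karen", "laura", "mary", "nancy", "olivia", "paula", "rachel",
    "sandra", "teresa", "vera", "wendy", "hannah", "maria", "linda", "susan",
    "emily", "alice", "carol", "donna", "edith", "flora",
)
_MALE_NAMES = (
    "adam", "brian", "carl", "david", "eric", "frank", "george", "henry",
    "ivan", "john", "kevin", "luke", "mark", "noah", "oscar", "peter",
    "robert", "samuel", "thomas", "victor", "walter", "james", "michael",
    "daniel", "paul", "albert", "edward", "felix", "harold", "martin",
)

# surname -> (majority ethnicity shares); remainder left for "other"
_SURNAME_SHARES = {
    "abbott": {"white": 0.91, "black": 0.03, "asian": 0.01, "hispanic": 0.03},
    "baker": {"white": 0.89, "black": 0.06, "asian": 0.01, "hispanic": 0.02},
    "carlson": {"white": 0.94, "black": 0.02, "asian": 0.01, "hispanic": 0.02},
    "dawson": {"white": 0.88, "black": 0.08, "asian": 0.01, "hispanic": 0.02},
    "elliott": {"white": 0.86, "black": 0.09, "asian": 0.01, "hispanic": 0.02},
    "foster": {"white": 0.85, "black": 0.11, "asian": 0.01, "hispanic": 0.02},
    "graham": {"white": 0.87, "black": 0.09, "asian": 0.01, "hispanic": 0.02},
    "holmes": {"white": 0.82, "black": 0.14, "asian": 0.01, "hispanic": 0.02},
    "washington": {"white": 0.05, "black": 0.90, "asian": 0.01, "hispanic": 0.02},
    "jefferson": {"white": 0.12, "black": 0.82, "asian": 0.01, "hispanic": 0.03},
    "boykins": {"white": 0.08, "black": 0.88, "asian": 0.01, "hispanic": 0.02},
    "smalls": {"white": 0.06, "black": 0.91, "asian": 0.01, "hispanic": 0.01},
    "nguyen": {"white": 0.02, "black": 0.01, "asian": 0.94, "hispanic": 0.02},
    "tran": {"white": 0.02, "black": 0.01, "asian": 0.93, "hispanic": 0.02},
    "huang": {"white": 0.02, "black": 0.01, "asian": 0.95, "hispanic": 0.01},
    "choi": {"white": 0.03, "black": 0.01, "asian": 0.92, "hispanic": 0.01},
    "patel": {"white": 0.02, "black": 0.01, "asian": 0.93, "hispanic": 0.01},
    "hernandez": {"white": 0.0455, "black": 0.0038, "asian": 0.0027, "hispanic": 0.9381},
    "garcia": {"white": 0.05, "black": 0.01, "asian": 0.01, "hispanic": 0.91},
    "ramirez": {"white": 0.04, "black": 0.01, "asian": 0.01, "hispanic": 0.92},
    "vasquez": {"white": 0.04, "black": 0.01, "asian": 0.01, "hispanic": 0.92},
    "fuentes": {"white": 0.05, "black": 0.01, "asian": 0.01, "hispanic": 0.90},
    "morales": {"white": 0.05, "black": 0.01, "asian": 0.01, "hispanic": 0.91},
}

_STATE_CITIES = (
    ("NY", "New York", ("new york ny", "ny ny", "brooklyn ny")),
    ("CA", "Los Angeles", ("los angeles ca", "san francisco ca")),
    ("TX", "Houston", ("houston tx", "austin tx")),
    ("FL", "Miami", ("miami fl", "orlando fl")),
    ("WA", "Seattle", ("seattle wa",)),
    ("IL", "Chicago", ("chicago il",)),
    ("MA", "Boston", ("boston ma",)),
    ("GA", "Atlanta", ("atlanta ga",)),
    ("CO", "Denver", ("denver co",)),
    ("AZ", "Phoenix", ("phoenix az",)),
    ("PA", "Philadelphia", ("philadelphia pa",)),
    ("OH", "Columbus", ("columbus oh",)),
)

_STATE_POPULATIONS = {
    "NY": 19_450_000, "CA": 39_500_000, "TX": 29_000_000, "FL": 21_500_000,
    "WA": 7_600_000, "IL": 12_670_000, "MA": 6_890_000, "GA": 10_600_000,
    "CO": 5_770_000, "AZ": 7_280_000, "PA": 12_800_000, "OH": 11_690_000,
}

_NON_US_ROWS = (
    ("paris france", "Paris", "", "FR"),
    ("london uk", "London", "", "GB"),
    ("toronto canada", "Toronto", "", "CA"),
)


@dataclass(frozen=True)
class FixturePaths:
    ssa_dir: Path
    census_file: Path
    gazetteer_file: Path
    populations_file: Path
    covariates_file: Path


def generate_reference_fixtures(
    out_dir: Union[str, Path],
    seed: int = 0,
    n_names: int = 40,
    n_surnames: int = 20,
    n_states: int = 10,
    year_start: int = 1990,
    year_end: int = 1995,
) -> FixturePaths:
    """Write every reference file the readers consume, in their dialects.

    The files deliberately exercise each filter branch: names at and
    just under the 10,000 aggregate-frequency cut, at and just under the
    95% probability cut, a unisex name, surnames at and under the 1000
    frequency and 80% majority cuts, a suppressed "(S)" cell, and the
    Hernandez row with its canonical share distribution.
    """
    if n_names < 10 or n_surnames < 10:
        raise ValueError("fixture sizes must be >= 10")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    ssa_dir = out_dir / "ssa"
    ssa_dir.mkdir(parents=True, exist_ok=True)

    # --- SSA yearly files -------------------------------------------------
    years = list(range(year_start, year_end + 1))
    n_f = (n_names + 1) // 2
    n_m = n_names - n_f
    regular = [(n, "F") for n in _FEMALE_NAMES[:n_f]] + [(n, "M") for n in _MALE_NAMES[:n_m]]
    rows_by_year: Dict[int, List[Tuple[str, str, int]]] = {y: [] for y in years}
    for name, code in regular:
        for y in years:
            dominant = int(rng.integers(1500, 4000))
            minority = int(rng.integers(0, max(2, dominant // 50)))
            rows_by_year[y].append((name, code, dominant))
            if minority > 0:
                rows_by_year[y].append((name, "M" if code == "F" else "F", minority))
    y0 = years[0]
    # engineered boundary names, single-year so their aggregates are exact
    rows_by_year[y0] += [
        ("edgefreq", "F", 10_000),       # aggregate exactly at the frequency cut
        ("underfreq", "F", 9_999),       # one below the cut
        ("edgeprob", "F", 19_000),       # 19000/20000 = 0.95 exactly
        ("edgeprob", "M", 1_000),
        ("underprob", "F", 9_490),       # 0.949 < 0.95
        ("underprob", "M", 510),
        ("robin", "F", 9_000),           # unisex, probability ~0.53
        ("robin", "M", 8_000),
        ("tinyname", "F", 120),          # far below the frequency cut
    ]
    for y in years:
        with open(ssa_dir / f"yob{y}.txt", "w", encoding="utf-8") as fh:
            for name, code, count in sorted(rows_by_year[y]):
                fh.write(f"{name.capitalize()},{code},{count}\n")

    # --- census surname file ---------------------------------------------
    census_file = out_dir / "census_surnames.csv"
    surnames = list(_SURNAME_SHARES.items())[:n_surnames]
    with open(census_file, "w", encoding="utf-8") as fh:
        fh.write("name,count,pctwhite,pctblack,pctapi,pcthispanic\n")

        def write_row(name, count, shares, suppressed=()):
            cells = []
            for eth in ("white", "black", "asian", "hispanic"):
                cells.append("(S)" if eth in suppressed else f"{shares[eth] * 100:.2f}")
            fh.write(f"{name.upper()},{count},{','.join(cells)}\n")

        for name, shares in surnames:
            count = 58_000 if name == "hernandez" else int(rng.integers(2_000, 90_000))
            write_row(name, count, shares)
        write_row("edgeeighty", 5_000,
                  {"white": 0.80, "black": 0.07, "asian": 0.03, "hispanic": 0.03})
        write_row("undereighty", 5_000,
                  {"white": 0.79, "black": 0.08, "asian": 0.03, "hispanic": 0.03})
        write_row("rarename", 999,
                  {"white": 0.99, "black": 0.003, "asian": 0.003, "hispanic": 0.003})
        write_row("suppressed", 4_000,
                  {"white": 0.90, "black": 0.04, "asian": 0.0, "hispanic": 0.02},
                  suppressed=("asian",))

    # --- gazetteer, populations, covariates -------------------------------
    states = _STATE_CITIES[:n_states]
    gazetteer_file = out_dir / "gazetteer.csv"
    with open(gazetteer_file, "w", encoding="utf-8") as fh:
        fh.write("normalized,city,state,country\n")
        for code, city, keys in states:
            for key in keys:
                city_name = " ".join(key.split()[:-1]).title() if key != "ny ny" else "New York"
                fh.write(f"{key},{city_name},{code},US\n")
        for key, city, state, country in _NON_US_ROWS:
            fh.write(f"{key},{city},{state},{country}\n")

    populations_file = out_dir / "state_populations.csv"
    with open(populations_file, "w", encoding="utf-8") as fh:
        fh.write("state,population\n")
        for code, _, _ in states:
            fh.write(f"{code},{_STATE_POPULATIONS[code]}\n")

    covariates_file = out_dir / "state_covariates.csv"
    with open(covariates_file, "w", encoding="utf-8") as fh:
        fh.write("state,population,internet_usage,physicians_per_capita,"
                 "uninsured_fraction,annual_income,education_fraction\n")
        for code, _, _ in states:
            fh.write(
                f"{code},{_STATE_POPULATIONS[code]},"
                f"{rng.uniform(0.65, 0.90):.4f},"
                f"{rng.uniform(0.0020, 0.0042):.6f},"
                f"{rng.uniform(0.06, 0.18):.4f},"
                f"{rng.uniform(45000, 78000):.0f},"
                f"{rng.uniform(0.24, 0.46):.4f}\n"
            )

    return FixturePaths(ssa_dir, census_file, gazetteer_file, populations_file, covariates_file)


# ---------------------------------------------------------------------------
# corpora


def _default_ethnicity_mix():
    return {"white": 0.733, "hispanic": 0.232, "asian": 0.032, "black": 0.003}


def _default_age_mix():
    return {"0-17": 0.0105, "18-34": 0.3113, "35-44": 0.2236, "45-64": 0.3684, "65+": 0.0862}


def _default_writing_targets():
    return {"0-5": 0.3042, "6-9": 0.6617, "10-16": 0.0341}


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic source."""

    n_users: int
    seed: int
    source: str = "synthetic"
    gender_mix: float = 0.7848  # fraction female
    ethnicity_mix: Dict[str, float] = field(default_factory=_default_ethnicity_mix)
    age_mix: Dict[str, float] = field(default_factory=_default_age_mix)
    age_range_fraction: float = 0.25  # one of four sources reports ranges
    writing_targets: Optional[Dict[str, float]] = field(default_factory=_default_writing_targets)
    state_weights: Optional[Dict[str, float]] = None  # None: uniform over gazetteer states
    missing_gender: float = 0.2   # ~80% of users report gender where supported
    missing_age: float = 0.39     # ~61% report age
    missing_location: float = 0.38  # ~62% report location
    gender_report_style: str = "reported"  # "reported" | "name"
    state_report_style: str = "string"  # "string" | "reported"
    noise_name_rate: float = 0.0  # fraction with out-of-table names
    sentences_per_user: int = 14

    def validate(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        for name, frac in (
            ("gender_mix", self.gender_mix),
            ("age_range_fraction", self.age_range_fraction),
            ("missing_gender", self.missing_gender),
            ("missing_age", self.missing_age),
            ("missing_location", self.missing_location),
            ("noise_name_rate", self.noise_name_rate),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for name, mix in (("ethnicity_mix", self.ethnicity_mix), ("age_mix", self.age_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} must be a probability mixture summing to 1")
        if self.writing_targets is not None:
            if abs(sum(self.writing_targets.values()) - 1.0) > 1e-9:
                raise ValueError("writing_targets must sum to 1")
        if self.gender_report_style not in ("reported", "name"):
            raise ValueError("gender_report_style must be 'reported' or 'name'")
        if self.state_report_style not in ("string", "reported"):
            raise ValueError("state_report_style must be 'string' or 'reported'")


def _quota_labels(mix: Dict[str, float], n: int, rng: np.random.Generator) -> List[str]:
    """Largest-remainder quota assignment, shuffled."""
    floors = {k: int(math.floor(f * n)) for k, f in mix.items()}
    remainder = n - sum(floors.values())
    by_frac = sorted(mix, key=lambda k: (-(mix[k] * n - floors[k]), k))
    for k in by_frac[:remainder]:
        floors[k] += 1
    labels = [k for k in sorted(mix) for _ in range(floors[k])]
    rng.shuffle(labels)
    return labels


def _quota_flags(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    flags[: int(round(rate * n))] = True
    rng.shuffle(flags)
    return flags


_NOISE_CONSONANTS = "qxzvkw"

_WRITING_TARGET_GRADE = {"0-5": 3.5, "6-9": 7.5, "10-16": 12.0}


def _noise_name(rng: np.random.Generator, table) -> str:
    while True:
        name = "".join(_NOISE_CONSONANTS[rng.integers(0, len(_NOISE_CONSONANTS))] for _ in range(6))
        if name not in table:
            return name


def generate_corpus(
    spec: CorpusSpec,
    gender_table,
    ethnicity_table,
    gazetteer: Dict[str, ResolvedLocation],
) -> Tuple[List[UserRecord], pd.DataFrame]:
    """Draw a user corpus per spec; returns (users, ground-truth frame).

    Display and screen names are sampled from table entries consistent
    with the user's true gender and ethnicity (or from out-of-table
    noise names at ``noise_name_rate``); ages are emitted as numbers or
    in-bracket ranges; locations as raw strings the normalizer must
    clean back to gazetteer keys; posts from the writing-target grades.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_users

    female_pool = sorted(k for k, e in gender_table.entries.items() if e.gender == "female")
    male_pool = sorted(k for k, e in gender_table.entries.items() if e.gender == "male")
    surname_pools: Dict[str, list] = {}
    for k, e in ethnicity_table.entries.items():
        surname_pools.setdefault(e.ethnicity, []).append(k)
    for pool in surname_pools.values():
        pool.sort()

    genders = _quota_labels({"female": spec.gender_mix, "male": 1 - spec.gender_mix}, n, rng)
    ethnicities = _quota_labels(spec.ethnicity_mix, n, rng)
    age_brackets = _quota_labels(spec.age_mix, n, rng)
    writing = (
        _quota_labels(spec.writing_targets, n, rng) if spec.writing_targets else [None] * n
    )

    us_states = sorted({loc.state for loc in gazetteer.values() if loc.is_us and loc.state})
    state_mix = spec.state_weights or {s: 1.0 / len(us_states) for s in us_states}
    total_w = sum(state_mix.values())
    state_mix = {s: w / total_w for s, w in state_mix.items()}
    states = _quota_labels(state_mix, n, rng)
    keys_by_state: Dict[str, list] = {}
    for key, loc in gazetteer.items():
        if loc.is_us and loc.state:
            keys_by_state.setdefault(loc.state, []).append(key)
    for keys in keys_by_state.values():
        keys.sort()

    miss_gender = _quota_flags(spec.missing_gender, n, rng)
    miss_age = _quota_flags(spec.missing_age, n, rng)
    miss_location = _quota_flags(spec.missing_location, n, rng)
    range_age = _quota_flags(spec.age_range_fraction, n, rng)
    noise_name = _quota_flags(spec.noise_name_rate, n, rng)

    bracket_bounds = {label: (lo, min(hi, 90)) for label, lo, hi in _age.BRACKETS}

    users: List[UserRecord] = []
    truth_rows = []
    for i in range(n):
        g, eth, ab, wb, st = genders[i], ethnicities[i], age_brackets[i], writing[i], states[i]

        if noise_name[i]:
            first = _noise_name(rng, gender_table)
            surname = _noise_name(rng, ethnicity_table)
        else:
            pool = female_pool if g == "female" else male_pool
            if not pool:
                raise ValueError(f"gender table has no {g} names to sample")
            if eth not in surname_pools:
                raise ValueError(f"ethnicity table has no {eth} surnames to sample")
            first = pool[rng.integers(0, len(pool))]
            surname = surname_pools[eth][rng.integers(0, len(surname_pools[eth]))]
        display_name = f"{first.capitalize()} {surname.capitalize()}"
        style = rng.integers(0, 3)
        num = rng.integers(10, 100)
        if style == 0:
            screen_name = f"{first}_{surname}{num}"
        elif style == 1:
            screen_name = f"{first.capitalize()}{surname.capitalize()}{num}"
        else:
            screen_name = f"{first}.{surname}"

        reported_gender = (
            g if (spec.gender_report_style == "reported" and not miss_gender[i]) else None
        )

        lo, hi = bracket_bounds[ab]
        if range_age[i]:
            width = int(rng.integers(3, 11))
            width = min(width, hi - lo)
            r_lo = int(rng.integers(lo, hi - width + 1)) if hi - width >= lo else lo
            reported_age = _age.AgeReport.range_(r_lo, r_lo + width)
            true_age = f"{r_lo}-{r_lo + width}"
        else:
            value = int(rng.integers(lo, hi + 1))
            reported_age = _age.AgeReport.exact(value)
            true_age = str(value)
        if miss_age[i]:
            reported_age = None

        location_string = None
        reported_state = None
        if not miss_location[i]:
            if spec.state_report_style == "reported":
                reported_state = st
            else:
                key = keys_by_state[st][rng.integers(0, len(keys_by_state[st]))]
                tokens = key.split()
                variant = rng.integers(0, 3)
                if variant == 0:
                    location_string = f"{' '.join(tokens[:-1]).title()}, {tokens[-1].upper()}"
                elif variant == 1:
                    location_string = key.upper() + "!!"
                else:
                    location_string = "  " + key + "  "

        posts: List[Post] = []
        if wb is not None:
            half = max(1, spec.sentences_per_user // 2)
            for part in range(2):
                n_sent = half if part == 0 else spec.sentences_per_user - half
                if n_sent > 0:
                    posts.append(
                        Post(generate_text_with_target_grade(_WRITING_TARGET_GRADE[wb], n_sent, rng))
                    )

        user_id = f"{spec.source}-{i:06d}"
        users.append(
            UserRecord(
                user_id=user_id,
                source=spec.source,
                display_name=display_name,
                screen_name=screen_name,
                reported_gender=reported_gender,
                reported_age=reported_age,
                location_string=location_string,
                reported_state=reported_state,
                posts=posts,
            )
        )
        truth_rows.append(
            {
                "user_id": user_id,
                "source": spec.source,
                "gender": g,
                "ethnicity": eth,
                "age": true_age,
                "age_bracket": ab,
                "state": st,
                "writing_bracket": wb,
                "name_in_table": not bool(noise_name[i]),
            }
        )

    truth = pd.DataFrame(truth_rows).set_index("user_id")
    return users, truth
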