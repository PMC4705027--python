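"""Distribution tables, significance tests, and per-capita correlations.

This module produces the reporting layer: per-source percentage tables
for gender / age group / ethnicity / writing bracket, pairwise
chi-square and Mann-Whitney significance matrices between sources, and
Pearson correlations between per-capita state participation and state
covariates (internet use, physicians, uninsured share, income,
education).

Conventions: percentages are over users with a *known* attribute;
fractional age user-equivalents flow through percentage tables as reals
but are rounded half-to-even before count-based chi-square tests;
p-values are two-sided with no multiple-testing correction by default
(a Bonferroni switch exists on the significance matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import age as _age
from .location import StateParticipation

GENDER = "gender"
AGE_GROUP = "age_group"
ETHNICITY = "ethnicity"
WRITING_BRACKET = "writing_bracket"
ATTRIBUTES = (GENDER, AGE_GROUP, ETHNICITY, WRITING_BRACKET)

_CATEGORY_ORDER = {
    GENDER: ("female", "male"),
    AGE_GROUP: _age.BRACKET_LABELS,
    ETHNICITY: ("white", "black", "asian", "hispanic"),
    WRITING_BRACKET: ("0-5", "6-9", "10-16"),
}

COVARIATE_COLUMNS = (
    "internet_usage",
    "physicians_per_capita",
    "uninsured_fraction",
    "annual_income",
    "education_fraction",
)


def load_covariates(path) -> pd.DataFrame:
    """Load the state covariate CSV, indexed by state code."""
    frame = pd.read_csv(path).set_index("state")
    missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"covariate file missing columns: {missing}")
    return frame


def profile_category(profile, attribute: str) -> Optional[str]:
    """The profile's category for an attribute, or None when unknown.

    Range-reported ages resolve to the bracket of the range midpoint
    here (point category for count/indicator tests); percentage tables
    use the proper fractional user-equivalents instead.
    """
    if attribute == GENDER:
        label = profile.gender.label
        return None if label == "unknown" else label
    if attribute == ETHNICITY:
        label = profile.ethnicity.label
        return None if label == "unknown" else label
    if attribute == WRITING_BRACKET:
        return profile.writing.bracket if profile.writing is not None else None
    if attribute == AGE_GROUP:
        point = _age.expected_age(profile.age)
        return None if point is None else _age.bracket_of(int(point))
    raise ValueError(f"unknown attribute {attribute!r}")


# ---------------------------------------------------------------------------
# distribution tables


@dataclass
class DistributionTable:
    """Per-source category percentages over users with the attribute known."""

    attribute: str
    percentages: Dict[str, Dict[str, float]] = field(default_factory=dict)
    base_n: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.percentages).T
        frame = frame.reindex(columns=list(_CATEGORY_ORDER[self.attribute]))
        frame.insert(0, "base_n", [self.base_n[s] for s in frame.index])
        frame.index.name = "source"
        return frame


def _group_by_source(profiles: Iterable) -> Dict[str, list]:
    groups: Dict[str, list] = {}
    for p in profiles:
        groups.setdefault(p.source, []).append(p)
    return groups


def distribution_table(profiles: Iterable, attribute: str) -> DistributionTable:
    """Percentage of each category per source, among known users.

    Sources with zero known users are omitted (with a warning via the
    returned table simply lacking them).  Age tables use fractional
    user-equivalents from uniform range redistribution.
    """
    table = DistributionTable(attribute=attribute)
    for source, group in _group_by_source(profiles).items():
        if attribute == AGE_GROUP:
            dist = _age.bin_ages(p.age for p in group)
            if dist.total == 0:
                continue
            table.percentages[source] = dist.percentages()
            table.base_n[source] = dist.total
        else:
            counts: Dict[str, int] = {c: 0 for c in _CATEGORY_ORDER[attribute]}
            n = 0
            for p in group:
                cat = profile_category(p, attribute)
                if cat is not None:
                    counts[cat] = counts.get(cat, 0) + 1
                    n += 1
            if n == 0:
                continue
            table.percentages[source] = {c: 100.0 * k / n for c, k in counts.items()}
            table.base_n[source] = n
    return table


# ---------------------------------------------------------------------------
# tests


def chi_square_independence(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, degrees of freedom, upper-tail p).  Rows or
    columns with zero margin raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p).

    ``exact`` enumerates the null distribution (valid without ties);
    ``normal_approx`` uses the normal approximation with tie and
    continuity corrections; ``auto`` picks exact when both samples have
    <= 8 observations and the pooled data are tie-free.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "normal_approx"
    scipy_method = {"exact": "exact", "normal_approx": "asymptotic"}[method]
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance sample")
    return float(sps.pearsonr(x, y).statistic)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    return float(sps.spearmanr(x, y).statistic)


def state_covariate_correlations(
    participation: Mapping[str, StateParticipation],
    covariates: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate per-capita rates with state covariates, per outlet.

    ``covariates`` is indexed by state code with the five covariate
    columns.  Correlations run over the states common to every outlet
    and the covariate matrix; fewer than 3 common states raises.
    """
    corr = {"pearson": pearson_correlation, "spearman": spearman_correlation}[method]
    common = set(covariates.index)
    for part in participation.values():
        common &= set(part.states)
    states = sorted(common)
    if len(states) < 3:
        raise ValueError(f"only {len(states)} states common to all inputs")
    cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
    out = {}
    for outlet, part in participation.items():
        rates = [part.states[s].rate for s in states]
        out[outlet] = {
            cov: corr(rates, covariates.loc[states, cov].to_numpy()) for cov in cols
        }
    frame = pd.DataFrame(out).T.reindex(columns=cols)
    frame.index.name = "outlet"
    return frame


def format_correlations(frame: pd.DataFrame) -> pd.DataFrame:
    """Round a correlation matrix to 2 decimals for reporting."""
    return frame.round(2)


# ---------------------------------------------------------------------------
# pairwise significance matrices


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


@dataclass
class StatsReport:
    """Pairwise significance results for one attribute.

    ``chi_square`` maps (source_a, source_b) -> (statistic, df, p) on
    the 2 x k category-count table; ``mann_whitney`` maps category ->
    (source_a, source_b) -> p from the test on per-user binary
    membership indicators.
    """

    attribute: str
    categories: Tuple[str, ...]
    chi_square: Dict[Tuple[str, str], Tuple[float, int, float]] = field(default_factory=dict)
    mann_whitney: Dict[str, Dict[Tuple[str, str], float]] = field(default_factory=dict)

    def chi_square_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": f"{a} vs {b}", "statistic": s, "df": d, "p": p}
            for (a, b), (s, d, p) in self.chi_square.items()
        ]
        return pd.DataFrame(rows)

    def mann_whitney_frame(self) -> pd.DataFrame:
        pairs = sorted({pair for by_pair in self.mann_whitney.values() for pair in by_pair})
        data = {
            f"{a} vs {b}": [self.mann_whitney[c].get((a, b), np.nan) for c in self.categories]
            for a, b in pairs
        }
        frame = pd.DataFrame(data, index=list(self.categories))
        frame.index.name = "category"
        return frame


def _category_counts(profiles: list, attribute: str) -> Optional[Dict[str, float]]:
    """Known-category counts for one source; None when nothing is known."""
    if attribute == AGE_GROUP:
        dist = _age.bin_ages(p.age for p in profiles)
        return dist.weights if dist.total > 0 else None
    counts = {c: 0.0 for c in _CATEGORY_ORDER[attribute]}
    n = 0
    for p in profiles:
        cat = profile_category(p, attribute)
        if cat is not None:
            counts[cat] += 1.0
            n += 1
    return counts if n else None


def significance_matrix(
    profiles: Iterable, attribute: str, bonferroni: bool = False
) -> StatsReport:
    """Pairwise chi-square and per-category Mann-Whitney p-values.

    For every ordered pair of sources with the attribute known: the
    chi-square test runs on the 2 x k table of category counts
    (fractional age user-equivalents rounded half-to-even); the
    Mann-Whitney test runs per category on the binary indicator samples
    (1 when a user belongs to the category).  With fewer than two
    eligible sources, raises.
    """
    categories = tuple(_CATEGORY_ORDER[attribute])
    groups = _group_by_source(profiles)
    eligible = {
        src: grp for src, grp in groups.items() if _category_counts(grp, attribute) is not None
    }
    if len(eligible) < 2:
        raise ValueError("significance matrix needs >= 2 sources with known attribute")
    report = StatsReport(attribute=attribute, categories=categories)
    report.mann_whitney = {c: {} for c in categories}
    n_pairs = len(list(combinations(eligible, 2)))
    m = (n_pairs * (1 + len(categories))) if bonferroni else 1

    for src_a, src_b in combinations(sorted(eligible), 2):
        counts_a = _category_counts(eligible[src_a], attribute)
        counts_b = _category_counts(eligible[src_b], attribute)
        obs = np.array(
            [
                [_round_half_even(counts_a[c]) for c in categories],
                [_round_half_even(counts_b[c]) for c in categories],
            ],
            dtype=float,
        )
        keep = obs.sum(axis=0) > 0  # drop empty categories, keep df honest
        stat, dof, p = chi_square_independence(obs[:, keep])
        report.chi_square[(src_a, src_b)] = (stat, dof, min(1.0, p * m))

        ind_a = {c: [] for c in categories}
        ind_b = {c: [] for c in categories}
        for grp, ind in ((eligible[src_a], ind_a), (eligible[src_b], ind_b)):
            for prof in grp:
                cat = profile_category(prof, attribute)
                if cat is None:
                    continue
                for c in categories:
                    ind[c].append(1.0 if c == cat else 0.0)
        for c in categories:
            if not ind_a[c] or not ind_b[c]:
                continue
            _, p = mann_whitney_u(ind_a[c], ind_b[c], method="auto")
            report.mann_whitney[c][(src_a, src_b)] = min(1.0, p * m)
    return report


def format_p(p: float) -> str:
    """Journal-style p formatting: '<.001' below a thousandth."""
    if p < 0.001:
        return "<.001"
    return f"{p:.4g}".lstrip("0") if p < 1 else "1.0"
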