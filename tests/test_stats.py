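"""Distribution tables, significance tests, correlations — each checked
against an independent oracle (closed form, enumeration, hand algebra)."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthdemog import (
    chi_square_independence,
    distribution_table,
    mann_whitney_u,
    pearson_correlation,
    significance_matrix,
    state_covariate_correlations,
)
from healthdemog.age import AgeReport
from healthdemog.ethnicity import EthnicityCall
from healthdemog.gender import GenderCall
from healthdemog.location import StateCount, StateParticipation
from healthdemog.pipeline import DemographicProfile

import pandas as pd


# ---------------------------------------------------------------------------
# oracles


def chi2_2x2_closed_form(a, b, c, d):
    """n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def mwu_exact_enumeration(sample_a, sample_b):
    """Brute-force exact two-sided Mann-Whitney p over all rank assignments.

    Enumerates every way the pooled observations could be split between
    the groups, computes U for each, and doubles the smaller tail
    (tie-free samples only).
    """
    na, nb = len(sample_a), len(sample_b)
    pooled = sorted(sample_a + sample_b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs_r = sum(ranks[v] for v in sample_a)
    obs_u = obs_r - na * (na + 1) / 2
    us = []
    for combo in combinations(range(1, na + nb + 1), na):
        us.append(sum(combo) - na * (na + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= obs_u)
    p_ge = np.mean(us >= obs_u)
    return obs_u, min(1.0, 2 * min(p_le, p_ge))


def _profile(uid, source, gender=None, ethnicity=None, age=None):
    return DemographicProfile(
        user_id=uid,
        source=source,
        gender=GenderCall(gender, "reported") if gender else GenderCall("unknown", "none"),
        ethnicity=EthnicityCall(ethnicity) if ethnicity else EthnicityCall("unknown"),
        age=age or AgeReport.missing(),
        writing=None,
        location=None,
        state=None,
        state_provenance="none",
    )


# ---------------------------------------------------------------------------
# distribution tables


class TestDistributionTable:
    def test_percentages_over_known_users(self):
        profiles = [_profile(f"u{i}", "s", gender="female") for i in range(3)]
        profiles.append(_profile("u3", "s", gender="male"))
        profiles.append(_profile("u4", "s"))  # unknown, excluded from base
        table = distribution_table(profiles, "gender")
        assert table.percentages["s"]["female"] == pytest.approx(75.0)
        assert table.percentages["s"]["male"] == pytest.approx(25.0)
        assert table.base_n["s"] == 4

    def test_all_unknown_source_omitted(self):
        table = distribution_table([_profile("u0", "s")], "gender")
        assert "s" not in table.percentages

    def test_age_table_uses_fractional_user_equivalents(self):
        profiles = [_profile("u0", "s", age=AgeReport.range_(35, 45))]
        table = distribution_table(profiles, "age_group")
        assert table.percentages["s"]["35-44"] == pytest.approx(100 * 10 / 11)
        assert table.percentages["s"]["45-64"] == pytest.approx(100 * 1 / 11)

    def test_quota_mixture_recovered_exactly(self, gender_table, ethnicity_table, gazetteer):
        from healthdemog import CorpusSpec, generate_corpus, profile_corpus

        spec = CorpusSpec(
            n_users=2500, seed=42, gender_mix=0.7848, gender_report_style="reported",
            missing_gender=0.0, writing_targets=None,
        )
        users, _ = generate_corpus(spec, gender_table, ethnicity_table, gazetteer)
        profiles = profile_corpus(users, gender_table, ethnicity_table, compute_writing=False)
        table = distribution_table(profiles, "gender")
        assert table.percentages["synthetic"]["female"] == pytest.approx(78.48, abs=1.0)


# ---------------------------------------------------------------------------
# chi-square


class TestChiSquare:
    def test_independent_table_gives_zero_statistic(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_2x2(self):
        stat, df, p = chi_square_independence([[20, 10], [10, 20]])
        assert stat == pytest.approx(6.6667, abs=1e-4)
        assert df == 1

    def test_df_formula(self):
        _, df, _ = chi_square_independence([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 5], [0, 7]])

    def test_agrees_with_2x2_closed_form_on_random_tables(self):
        rng = np.random.default_rng(1234)
        for _ in range(500):
            a, b, c, d = rng.integers(1, 200, size=4)
            stat, _, _ = chi_square_independence([[a, b], [c, d]])
            assert stat == pytest.approx(chi2_2x2_closed_form(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_interleaved_example_exact_p(self):
        u, p = mann_whitney_u([1, 3], [2, 4])
        assert u == 1.0
        assert p == pytest.approx(2 / 3, abs=1e-9)

    def test_identical_samples_p_one_under_normal_approx(self):
        _, p = mann_whitney_u([1.0] * 10, [1.0] * 10)
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for na in range(1, 7):
            for nb in range(1, 7):
                pooled = rng.permutation(np.arange(1, na + nb + 1, dtype=float))
                a, b = list(pooled[:na]), list(pooled[na:])
                u, p = mann_whitney_u(a, b, method="exact")
                oracle_u, oracle_p = mwu_exact_enumeration(a, b)
                assert u == pytest.approx(oracle_u)
                assert p == pytest.approx(oracle_p, abs=1e-9)

    @given(
        a=st.lists(st.integers(0, 1000), min_size=1, max_size=8, unique=True),
        b=st.lists(st.integers(1001, 2000), min_size=1, max_size=8, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_u_statistics_sum_to_product_for_tie_free_samples(self, a, b):
        af = [float(x) for x in a]
        bf = [float(x) + 0.5 for x in b]
        ua, _ = mann_whitney_u(af, bf)
        ub, _ = mann_whitney_u(bf, af)
        assert ua + ub == pytest.approx(len(a) * len(b))


# ---------------------------------------------------------------------------
# correlations


class TestCorrelations:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_covariance_hand_computation(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert pearson_correlation(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_correlation(x, y)
        assert pearson_correlation(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-12)
        assert pearson_correlation(x, 0.1 * y - 2.0) == pytest.approx(r, abs=1e-12)


def _participation(rates_by_state, population=1_000_000):
    return StateParticipation(
        states={
            s: StateCount(r * population, population, r) for s, r in rates_by_state.items()
        }
    )


class TestStateCovariateCorrelations:
    def _covariates(self, states, rng):
        return pd.DataFrame(
            {
                "internet_usage": rng.uniform(0.6, 0.9, len(states)),
                "physicians_per_capita": rng.uniform(0.002, 0.004, len(states)),
                "uninsured_fraction": rng.uniform(0.05, 0.2, len(states)),
                "annual_income": rng.uniform(40000, 80000, len(states)),
                "education_fraction": rng.uniform(0.2, 0.5, len(states)),
            },
            index=states,
        )

    def test_identical_covariate_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        states = [f"S{i}" for i in range(10)]
        cov = self._covariates(states, rng)
        rates = {s: cov.loc[s, "internet_usage"] * 1e-5 for s in states}
        result = state_covariate_correlations({"outlet": _participation(rates)}, cov)
        assert result.loc["outlet", "internet_usage"] == pytest.approx(1.0)

    def test_linear_plus_small_noise_recovers_strong_correlation(self):
        rng = np.random.default_rng(21)
        states = [f"S{i}" for i in range(30)]
        cov = self._covariates(states, rng)
        rates = {
            s: 2.0 * cov.loc[s, "physicians_per_capita"]
            + rng.normal(0, 1e-5)
            for s in states
        }
        result = state_covariate_correlations({"o": _participation(rates)}, cov)
        assert result.loc["o", "physicians_per_capita"] > 0.95

    def test_independent_covariate_stays_near_zero(self):
        rng = np.random.default_rng(2026)
        states = [f"S{i}" for i in range(51)]
        cov = self._covariates(states, rng)
        rates = {s: rng.uniform(1e-6, 1e-4) for s in states}
        result = state_covariate_correlations({"o": _participation(rates)}, cov)
        assert abs(result.loc["o", "annual_income"]) < 0.4

    def test_too_few_common_states_rejected(self):
        rng = np.random.default_rng(3)
        cov = self._covariates(["A", "B"], rng)
        with pytest.raises(ValueError):
            state_covariate_correlations({"o": _participation({"A": 1e-5, "B": 2e-5})}, cov)


# ---------------------------------------------------------------------------
# significance matrices


class TestSignificanceMatrix:
    def _two_sources(self, share_a, share_b, n):
        profiles = []
        for src, share in (("a", share_a), ("b", share_b)):
            nf = int(round(share * n))
            for i in range(n):
                profiles.append(
                    _profile(f"{src}{i}", src, gender="female" if i < nf else "male")
                )
        return profiles

    def test_identical_sources_are_not_significant(self):
        report = significance_matrix(self._two_sources(0.6, 0.6, 500), "gender")
        stat, _, p = report.chi_square[("a", "b")]
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        for cat in ("female", "male"):
            assert report.mann_whitney[cat][("a", "b")] > 0.9

    def test_divergent_mixtures_highly_significant(self):
        report = significance_matrix(self._two_sources(0.78, 0.52, 2000), "gender")
        _, _, p = report.chi_square[("a", "b")]
        assert p < 0.001
        assert report.mann_whitney["female"][("a", "b")] < 0.001

    def test_single_source_rejected(self):
        with pytest.raises(ValueError):
            significance_matrix(self._two_sources(0.6, 0.6, 10)[:10], "gender")

    def test_binary_indicator_symmetry(self):
        """For a two-category attribute both categories carry the same test."""
        report = significance_matrix(self._two_sources(0.7, 0.5, 300), "gender")
        assert report.mann_whitney["female"][("a", "b")] == pytest.approx(
            report.mann_whitney["male"][("a", "b")]
        )

    def test_age_user_equivalents_rounded_for_counts(self):
        profiles = [
            _profile(f"a{i}", "a", age=AgeReport.range_(35, 45)) for i in range(40)
        ] + [_profile(f"b{i}", "b", age=AgeReport.exact(30)) for i in range(40)]
        report = significance_matrix(profiles, "age_group")
        stat, df, p = report.chi_square[("a", "b")]
        assert math.isfinite(stat) and p <= 1.0
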