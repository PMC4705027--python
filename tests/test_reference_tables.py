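"""Gender/ethnicity lookup-table construction and its threshold filters."""

import io
from collections import defaultdict

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthdemog import (
    FormatError,
    build_ethnicity_table,
    build_gender_table,
    read_census_surname_file,
    read_ssa_year_file,
)
from healthdemog.reference_tables import SurnameDistributionRecord, YearlyNameRecord


class TestReadSsaYearFile:
    def test_parses_rows_into_cleaned_records(self):
        result = read_ssa_year_file(io.StringIO("Mary,F,55000\n"), 1950)
        assert result.records == [YearlyNameRecord("mary", "female", 55000, 1950)]
        assert result.skipped == 0

    def test_empty_file_is_a_format_error(self):
        with pytest.raises(FormatError):
            read_ssa_year_file(io.StringIO(""), 1950)

    def test_malformed_rows_are_skipped_and_counted(self):
        stream = io.StringIO("Mary,F,55000\nOops,Q,12\nJohn,M,abc\nAnna,F,100\n")
        result = read_ssa_year_file(stream, 1990)
        assert [r.name for r in result.records] == ["mary", "anna"]
        assert result.skipped == 2


class TestBuildGenderTable:
    def test_aggregates_and_computes_discriminative_probability(self):
        records = [
            YearlyNameRecord("anna", "female", 20000, 1990),
            YearlyNameRecord("anna", "male", 500, 1990),
        ]
        table = build_gender_table(records)
        entry = table.get("anna")
        assert entry.gender == "female"
        assert entry.total_frequency == 20500
        assert entry.probability == pytest.approx(20000 / 20500)

    def test_low_probability_name_excluded_despite_high_frequency(self):
        records = [
            YearlyNameRecord("robin", "female", 9000, 1990),
            YearlyNameRecord("robin", "male", 8000, 1990),
        ]
        assert len(build_gender_table(records)) == 0

    def test_thresholds_keep_at_boundary(self, gender_table):
        # fixture names engineered at the exact cut points
        assert "edgefreq" in gender_table  # aggregate frequency exactly 10,000
        assert "underfreq" not in gender_table  # 9,999
        assert "edgeprob" in gender_table  # probability exactly 0.95
        assert gender_table.get("edgeprob").probability == pytest.approx(0.95)
        assert "underprob" not in gender_table  # 0.949

    def test_empty_input_yields_empty_table(self):
        assert len(build_gender_table([])) == 0

    def test_top_k_per_year_restricts_to_rank_cut(self):
        records = [
            YearlyNameRecord("aaa", "female", 30000, 1990),
            YearlyNameRecord("bbb", "female", 20000, 1990),
            YearlyNameRecord("ccc", "female", 15000, 1990),
        ]
        table = build_gender_table(records, top_k_per_year=2)
        assert set(table.entries) == {"aaa", "bbb"}

    def test_aggregation_matches_bruteforce_sum(self, ssa_records, gender_table):
        totals = defaultdict(int)
        for r in ssa_records:
            totals[r.name] += r.count
        for name, entry in gender_table.entries.items():
            assert entry.total_frequency == totals[name]

    def test_serialization_round_trips_byte_identically(self, gender_table, tmp_path):
        from healthdemog import GenderNameTable

        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        gender_table.to_tsv(p1)
        reloaded = GenderNameTable.from_tsv(p1)
        assert reloaded.entries == gender_table.entries
        assert reloaded.build_params == gender_table.build_params
        reloaded.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestReadCensusSurnameFile:
    def test_hernandez_row_parses_to_printed_shares(self, surname_records):
        rec = next(r for r in surname_records if r.surname == "hernandez")
        assert rec.shares == pytest.approx(
            {"white": 0.0455, "black": 0.0038, "asian": 0.0027, "hispanic": 0.9381}
        )

    def test_suppressed_cells_read_as_zero(self, surname_records):
        rec = next(r for r in surname_records if r.surname == "suppressed")
        assert rec.shares["asian"] == 0.0

    def test_missing_columns_raise_format_error(self):
        with pytest.raises(FormatError):
            read_census_surname_file(io.StringIO("name,count\nSMITH,100\n"))

    def test_two_row_fixture_round_trips(self):
        text = (
            "name,count,pctwhite,pctblack,pctapi,pcthispanic\n"
            "SMITH,5000,70.90,23.11,0.50,2.19\n"
            "GARCIA,4000,5.00,0.49,1.41,90.81\n"
        )
        records = read_census_surname_file(io.StringIO(text))
        assert [r.surname for r in records] == ["smith", "garcia"]


class TestBuildEthnicityTable:
    def test_hernandez_classified_hispanic_with_majority_share(self, ethnicity_table):
        entry = ethnicity_table.get("hernandez")
        assert entry.ethnicity == "hispanic"
        assert entry.probability == pytest.approx(0.9381)

    def test_majority_threshold_keep_at_boundary(self, ethnicity_table):
        assert "edgeeighty" in ethnicity_table  # majority share exactly 0.80
        assert "undereighty" not in ethnicity_table  # 0.79

    def test_frequency_threshold_excludes_rare_surnames(self, ethnicity_table):
        assert "rarename" not in ethnicity_table  # frequency 999, share 0.99

    def test_tied_majority_share_drops_record(self):
        rec = SurnameDistributionRecord(
            "tieone", 5000, {"white": 0.45, "black": 0.45, "asian": 0.05, "hispanic": 0.05}
        )
        table = build_ethnicity_table([rec], min_majority_probability=0.4)
        assert "tieone" not in table


@st.composite
def _name_record_sets(draw):
    names = draw(st.lists(st.sampled_from(["ada", "ben", "cai", "dee", "eli"]), min_size=1, max_size=12))
    records = []
    for i, name in enumerate(names):
        gender = draw(st.sampled_from(["male", "female"]))
        count = draw(st.integers(min_value=0, max_value=30000))
        records.append(YearlyNameRecord(name, gender, count, 1990 + (i % 3)))
    return records


@given(records=_name_record_sets(), df=st.integers(0, 20000), dp=st.floats(0.5, 1.0))
@settings(max_examples=60, deadline=None)
def test_gender_filter_is_monotone_in_both_thresholds(records, df, dp):
    """Raising either threshold never adds an entry (subset property)."""
    base = set(build_gender_table(records, min_frequency=df, min_probability=dp).entries)
    tighter_f = set(build_gender_table(records, min_frequency=df + 1000, min_probability=dp).entries)
    tighter_p = set(
        build_gender_table(records, min_frequency=df, min_probability=min(1.0, dp + 0.02)).entries
    )
    assert tighter_f <= base
    assert tighter_p <= base
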