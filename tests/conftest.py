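"""Shared fixtures: generated reference files, built tables, small corpora."""

import pytest

from healthdemog import (
    build_ethnicity_table,
    build_gender_table,
    load_gazetteer,
    load_populations,
    read_census_surname_file,
    read_ssa_directory,
)
from healthdemog.synthetic import generate_reference_fixtures


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("refdata")
    return generate_reference_fixtures(out, seed=7)


@pytest.fixture(scope="session")
def ssa_records(fixture_paths):
    return read_ssa_directory(fixture_paths.ssa_dir, 1990, 1995)


@pytest.fixture(scope="session")
def gender_table(ssa_records):
    return build_gender_table(ssa_records)


@pytest.fixture(scope="session")
def surname_records(fixture_paths):
    return read_census_surname_file(fixture_paths.census_file)


@pytest.fixture(scope="session")
def ethnicity_table(surname_records):
    return build_ethnicity_table(surname_records)


@pytest.fixture(scope="session")
def gazetteer(fixture_paths):
    return load_gazetteer(fixture_paths.gazetteer_file)


@pytest.fixture(scope="session")
def populations(fixture_paths):
    return load_populations(fixture_paths.populations_file)
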