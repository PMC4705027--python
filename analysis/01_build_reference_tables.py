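#!/usr/bin/env python
"""Generate the reference fixture files and build the classifier tables.

Writes SSA-style yearly name files, a census-style surname file, the
offline gazetteer, state populations and covariates under
results/refdata/, then builds and saves the filtered gender and
ethnicity lookup tables (thresholds: 10,000 / 95% for names, 1000 / 80%
for surnames) under results/tables/.
"""

from pathlib import Path

from healthdemog import (
    build_ethnicity_table,
    build_gender_table,
    read_census_surname_file,
    read_ssa_directory,
)
from healthdemog.synthetic import generate_reference_fixtures

ROOT = Path(__file__).resolve().parents[1]
REFDATA = ROOT / "results" / "refdata"
TABLES = ROOT / "results" / "tables"
SEED = 20150806


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    paths = generate_reference_fixtures(REFDATA, seed=SEED)
    print(f"reference fixtures written under {REFDATA}")

    records = read_ssa_directory(paths.ssa_dir, 1990, 1995)
    unique = len({r.name for r in records})
    gender_table = build_gender_table(records)
    gender_table.to_tsv(TABLES / "gender_names.tsv")
    print(
        f"gender table: {unique} unique names in the yearly files, "
        f"{len(gender_table)} retained after the 10,000 / 95% filters"
    )

    surnames = read_census_surname_file(paths.census_file)
    ethnicity_table = build_ethnicity_table(surnames)
    ethnicity_table.to_tsv(TABLES / "surname_ethnicities.tsv")
    print(
        f"ethnicity table: {len(surnames)} surname rows, "
        f"{len(ethnicity_table)} retained after the 1000 / 80% filters"
    )
    hernandez = ethnicity_table.get("hernandez")
    print(
        f"worked example: hernandez -> {hernandez.ethnicity} "
        f"(majority probability {hernandez.probability:.2%})"
    )


if __name__ == "__main__":
    main()
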