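#!/usr/bin/env python
"""Tabulate the demographic distributions per outlet.

Produces the percentage tables for gender, age group, ethnicity and
writing-level bracket (percentages over users with the attribute known,
age in fractional user-equivalents) and writes one CSV per attribute
under results/tables/.
"""

from pathlib import Path

import pandas as pd

from healthdemog import distribution_table
from healthdemog.pipeline import profiles_from_frame
from healthdemog.stats import ATTRIBUTES

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    profiles = profiles_from_frame(pd.read_csv(RESULTS / "profiles.csv"))
    for attribute in ATTRIBUTES:
        table = distribution_table(profiles, attribute)
        frame = table.to_frame().round(2)
        out = RESULTS / "tables" / f"distribution_{attribute}.csv"
        frame.to_csv(out)
        print(f"\n{attribute} distribution (% of users with known attribute):")
        print(frame.to_string())
    print(f"\ntables written under {RESULTS / 'tables'}")


if __name__ == "__main__":
    main()
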