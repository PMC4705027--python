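#!/usr/bin/env python
"""Run the demographic classifiers over every simulated corpus.

For each corpus: resolve gender (reported > first name > screen name),
classify ethnicity from surnames, parse ages, compute the modified
Flesch-Kincaid writing level, and resolve US states (reported state or
frequency-filtered, geocoded location strings).  Reports classifier
accuracy against the generator's ground truth and writes the flattened
profiles to results/profiles.csv.
"""

from pathlib import Path

import pandas as pd

from healthdemog import (
    GenderNameTable,
    SurnameEthnicityTable,
    load_gazetteer,
    profile_corpus,
    read_corpus,
)
from healthdemog.pipeline import profiles_to_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    gender_table = GenderNameTable.from_tsv(RESULTS / "tables" / "gender_names.tsv")
    ethnicity_table = SurnameEthnicityTable.from_tsv(
        RESULTS / "tables" / "surname_ethnicities.tsv"
    )
    gazetteer = load_gazetteer(RESULTS / "refdata" / "gazetteer.csv")
    truth = pd.read_csv(RESULTS / "corpora" / "ground_truth.csv").set_index("user_id")

    all_profiles = []
    for path in sorted((RESULTS / "corpora").glob("*.jsonl")):
        users = read_corpus(path).records
        profiles = profile_corpus(users, gender_table, ethnicity_table, gazetteer)
        all_profiles.extend(profiles)
        frame = profiles_to_frame(profiles)

        merged = frame.set_index("user_id").join(truth, rsuffix="_true")
        known = merged[merged["gender"] != "unknown"]
        acc = (known["gender"] == known["gender_true"]).mean() if len(known) else float("nan")
        coverage = len(known) / len(merged)
        print(
            f"{path.stem}: gender coverage {coverage:.1%}, "
            f"accuracy on resolved users {acc:.1%}"
        )

    out = RESULTS / "profiles.csv"
    profiles_to_frame(all_profiles).to_csv(out, index=False)
    print(f"profiles written to {out}")


if __name__ == "__main__":
    main()
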