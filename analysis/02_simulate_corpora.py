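#!/usr/bin/env python
"""Simulate four health-outlet corpora with known ground truth.

One corpus per outlet type, each with the demographic mixtures such
outlets exhibit: a Twitter-like source (gender and ethnicity only
inferable from names, free-text locations, no ages), a Google+-like
source (reported gender and age), and drug-review / health-forum
sources (strongly female, older, state reported directly, ethnicity not
classifiable because real names are absent).  State weights are tilted
by a covariate per outlet so the location analysis downstream has a
disparity signal to find.

Writes JSONL corpora and ground-truth CSVs under results/corpora/.
"""

from pathlib import Path

import pandas as pd

from healthdemog import (
    CorpusSpec,
    GenderNameTable,
    SurnameEthnicityTable,
    generate_corpus,
    load_gazetteer,
    write_corpus,
)

ROOT = Path(__file__).resolve().parents[1]
REFDATA = ROOT / "results" / "refdata"
TABLES = ROOT / "results" / "tables"
OUT = ROOT / "results" / "corpora"
SEED = 20150806

# per-outlet study conditions: (n, female share, age mix, writing mix,
# ethnicity classifiable?, gender/state reporting styles)
SOURCES = {
    "twitter_health": dict(
        n_users=1500,
        gender_mix=0.5181,
        ethnicity_mix={"white": 0.7297, "hispanic": 0.2349, "asian": 0.0324, "black": 0.0030},
        age_mix=None,  # ages unavailable on this outlet
        writing_targets={"0-5": 0.3777, "6-9": 0.5110, "10-16": 0.1113},
        gender_report_style="name",
        state_report_style="string",
        tilt="physicians_per_capita",
    ),
    "gplus_health": dict(
        n_users=800,
        gender_mix=0.3536,
        ethnicity_mix={"white": 0.767, "hispanic": 0.174, "asian": 0.056, "black": 0.003},
        age_mix={"0-17": 0.0342, "18-34": 0.5321, "35-44": 0.2189, "45-64": 0.1902, "65+": 0.0246},
        writing_targets={"0-5": 0.0645, "6-9": 0.5564, "10-16": 0.3791},
        gender_report_style="reported",
        state_report_style="string",
        tilt="physicians_per_capita",
    ),
    "drug_reviews": dict(
        n_users=1000,
        gender_mix=0.7848,
        ethnicity_mix=None,  # no real names on review sites
        age_mix={"0-17": 0.0105, "18-34": 0.3113, "35-44": 0.2236, "45-64": 0.3684, "65+": 0.0862},
        writing_targets={"0-5": 0.3042, "6-9": 0.6617, "10-16": 0.0341},
        gender_report_style="reported",
        state_report_style="reported",
        age_ranges=True,  # the DailyStrength-style source reports ranges
        tilt="annual_income",
    ),
    "health_forums": dict(
        n_users=1000,
        gender_mix=0.7841,
        ethnicity_mix=None,
        age_mix={"0-17": 0.0103, "18-34": 0.3980, "35-44": 0.2581, "45-64": 0.2895, "65+": 0.0441},
        writing_targets={"0-5": 0.2878, "6-9": 0.6824, "10-16": 0.0298},
        gender_report_style="reported",
        state_report_style="reported",
        tilt="annual_income",
    ),
}


def tilted_state_weights(covariates: pd.DataFrame, column: str) -> dict:
    """Population-proportional weights, boosted up to 2x along a covariate."""
    cov = covariates[column]
    scaled = (cov - cov.min()) / (cov.max() - cov.min())
    weights = covariates["population"] * (1.0 + scaled)
    return (weights / weights.sum()).to_dict()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gender_table = GenderNameTable.from_tsv(TABLES / "gender_names.tsv")
    ethnicity_table = SurnameEthnicityTable.from_tsv(TABLES / "surname_ethnicities.tsv")
    gazetteer = load_gazetteer(REFDATA / "gazetteer.csv")
    covariates = pd.read_csv(REFDATA / "state_covariates.csv").set_index("state")

    truths = []
    for i, (source, cond) in enumerate(SOURCES.items()):
        spec = CorpusSpec(
            n_users=cond["n_users"],
            seed=SEED + i,
            source=source,
            gender_mix=cond["gender_mix"],
            writing_targets=cond["writing_targets"],
            gender_report_style=cond["gender_report_style"],
            state_report_style=cond["state_report_style"],
            state_weights=tilted_state_weights(covariates, cond["tilt"]),
            age_range_fraction=1.0 if cond.get("age_ranges") else 0.0,
            noise_name_rate=0.0 if cond["ethnicity_mix"] is not None else 1.0,
            missing_location=0.38,
            missing_age=1.0 if cond["age_mix"] is None else 0.39,
        )
        if cond["ethnicity_mix"] is not None:
            spec.ethnicity_mix = cond["ethnicity_mix"]
        if cond["age_mix"] is not None:
            spec.age_mix = cond["age_mix"]
        users, truth = generate_corpus(spec, gender_table, ethnicity_table, gazetteer)
        write_corpus(users, OUT / f"{source}.jsonl")
        truths.append(truth.reset_index())
        print(f"{source}: {len(users)} users written")

    pd.concat(truths).to_csv(OUT / "ground_truth.csv", index=False)
    print(f"ground truth for {sum(len(t) for t in truths)} users written")


if __name__ == "__main__":
    main()
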