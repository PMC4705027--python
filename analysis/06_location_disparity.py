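#!/usr/bin/env python
"""Per-capita state participation and its covariate correlations.

Counts the users resolved to each US state per outlet, normalizes by
state population, and correlates the per-capita rates with the state
covariates (internet use, physicians per capita, uninsured share,
income, education).  Writes rates and the correlation matrix under
results/stats/.
"""

from pathlib import Path

import pandas as pd

from healthdemog import load_covariates, load_populations, per_capita_by_state
from healthdemog.pipeline import profiles_from_frame
from healthdemog.stats import format_correlations, state_covariate_correlations

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    out_dir = RESULTS / "stats"
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = profiles_from_frame(pd.read_csv(RESULTS / "profiles.csv"))
    populations = load_populations(RESULTS / "refdata" / "state_populations.csv")
    covariates = load_covariates(RESULTS / "refdata" / "state_covariates.csv")

    participation = {}
    rate_rows = []
    for source in sorted({p.source for p in profiles}):
        part = per_capita_by_state((p for p in profiles if p.source == source), populations)
        participation[source] = part
        print(f"{source}: {part.total_users():.0f} users resolved to a state")
        for state, count in part.states.items():
            rate_rows.append(
                {"source": source, "state": state, "users": count.user_count,
                 "population": count.population, "per_capita_rate": count.rate}
            )
    pd.DataFrame(rate_rows).to_csv(out_dir / "state_rates.csv", index=False)

    corr = format_correlations(state_covariate_correlations(participation, covariates))
    corr.to_csv(out_dir / "covariate_correlations.csv")
    print("\ncorrelation of per-capita rates with state covariates:")
    print(corr.to_string())
    print(f"\nlocation outputs written under {out_dir}")


if __name__ == "__main__":
    main()
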