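#!/usr/bin/env python
"""Pairwise significance tests between outlets.

For every pair of outlets and each demographic attribute: Pearson's
chi-square test of independence on the category-count table, and the
Mann-Whitney U test per category on binary membership indicators.
Writes one chi-square and one Mann-Whitney CSV per attribute under
results/stats/.
"""

from pathlib import Path

import pandas as pd

from healthdemog import significance_matrix
from healthdemog.pipeline import profiles_from_frame
from healthdemog.stats import ATTRIBUTES, format_p

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    out_dir = RESULTS / "stats"
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = profiles_from_frame(pd.read_csv(RESULTS / "profiles.csv"))

    for attribute in ATTRIBUTES:
        try:
            report = significance_matrix(profiles, attribute)
        except ValueError as exc:
            print(f"{attribute}: skipped ({exc})")
            continue
        chi = report.chi_square_frame()
        chi["p_formatted"] = chi["p"].map(format_p)
        chi.to_csv(out_dir / f"chi_square_{attribute}.csv", index=False)
        mwu = report.mann_whitney_frame()
        mwu.to_csv(out_dir / f"mann_whitney_{attribute}.csv")
        print(f"\n{attribute}: chi-square p-values")
        print(chi[["pair", "p_formatted"]].to_string(index=False))
    print(f"\nstats written under {out_dir}")


if __name__ == "__main__":
    main()
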