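#!/usr/bin/env python
"""Response factors and transcript/translation concordance.

Reads results/fold_changes.tsv, scales each feature's H-shift fold changes
by the extreme reaction of its sign, sums them into the response factors
R_transcript and R_de_novo, classifies features against the diagonal band
(|ΔR| ≤ 0.5 = concordant) and compares the estimated discordant fraction
with the planted ground truth.
"""

from pathlib import Path

import pandas as pd

from retroflux.concordance import (response_factor_table, classify_concordance,
                                   translational_control_fraction,
                                   plot_concordance)
from retroflux.normalize import read_foldchange_tsv

BASE = Path(__file__).resolve().parents[1] / "results"
CUTOFF = 0.5


def main() -> None:
    fc = read_foldchange_tsv(BASE / "fold_changes.tsv")
    table = classify_concordance(response_factor_table(fc), cutoff=CUTOFF)
    table.to_csv(BASE / "response_factors.tsv", sep="\t")
    plot_concordance(table, CUTOFF, BASE / "concordance.png")

    fraction, n_disc, n_total = translational_control_fraction(table)
    print(f"{n_disc} of {n_total} features discordant "
          f"(fraction {fraction:.3f}, cutoff |ΔR| > {CUTOFF})")

    truth_path = BASE / "simulated" / "ground_truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="spot_id")
        planted = 1.0 - truth.loc[table.index, "concordant"].mean()
        agree = ((table["call"] == "discordant")
                 == ~truth.loc[table.index, "concordant"]).mean()
        print(f"planted discordant fraction among scored features: {planted:.3f}; "
              f"per-feature call agreement with truth: {agree:.3f}")
    print(f"table → {BASE / 'response_factors.tsv'}")


if __name__ == "__main__":
    main()
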