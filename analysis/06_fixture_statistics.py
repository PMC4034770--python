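#!/usr/bin/env python
"""Derived statistics from the packaged reference tables.

Recomputes the small arithmetic facts the study reports from its printed
tables: treatment physiology ratios, catalog counts, the chloroplast
localization share and the headline percentages; writes
results/fixture_statistics.tsv.
"""

from pathlib import Path

import pandas as pd

from retroflux import fixtures

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    physiology = fixtures.load_physiology()
    proteins = fixtures.load_proteins()
    rows = []

    for parameter in ("rna", "protein", "chlorophyll"):
        pct = fixtures.ratio_to_reference(physiology, parameter, "L", "N")
        rows.append((f"{parameter}_L_vs_N_percent", pct))

    rows.append(("identified_polypeptides", fixtures.count_records(proteins)))
    rows.append(("not_detected_in_autoradiogram",
                 fixtures.count_not_detected(proteins)))
    rows.append(("chloroplast_localized_percent",
                 fixtures.fraction_localized(proteins, "chloroplast")))

    # headline set percentages: deviating spots per condition over the
    # 129-spot significant universe, and regulated transcripts over the
    # 42 quantified identified proteins
    for label, count, universe in (("n_plants_deviating_percent", 26, 129),
                                   ("l_plants_deviating_percent", 64, 129),
                                   ("h_shift_deviating_percent", 28, 129),
                                   ("regulated_transcripts_percent", 27, 42)):
        rows.append((label, fixtures.percent_of(count, universe)))

    table = pd.DataFrame(rows, columns=["statistic", "value"])
    BASE.mkdir(parents=True, exist_ok=True)
    table.to_csv(BASE / "fixture_statistics.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"→ {BASE / 'fixture_statistics.tsv'}")


if __name__ == "__main__":
    main()
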