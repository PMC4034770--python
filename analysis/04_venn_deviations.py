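#!/usr/bin/env python
"""Deviation-from-average bookkeeping over the significant spots.

Reads the ordered (z-scored) heat-map matrix, builds per-condition sets of
spots whose mean standardized intensity deviates from the all-treatment
average by at least theta, decomposes them into exclusive Venn regions and
writes results/venn_report.tsv plus an UpSet-style region plot.
"""

from pathlib import Path

import pandas as pd

from retroflux.venn import deviation_sets, venn_counts, region_plot, write_report_tsv

BASE = Path(__file__).resolve().parents[1] / "results"
THETA = 1.0


def main() -> None:
    z = pd.read_csv(BASE / "heatmap_matrix.tsv", sep="\t", index_col="spot_id")
    z = z.drop(columns=["cluster"])
    sets = deviation_sets(z, theta=THETA)
    report = venn_counts(sets, universe_size=len(z), universe=z.index)
    write_report_tsv(report, BASE / "venn_report.tsv")
    region_plot(report, BASE / "venn_regions.png")

    print(f"deviation sets at theta = {THETA} over {len(z)} significant spots:")
    for cond in report.conditions:
        print(f"  {cond}: {report.totals[cond]} deviating "
              f"({report.percentages[cond]}% of universe), "
              f"{report.specific(cond)} condition-specific")
    print(f"report → {BASE / 'venn_report.tsv'}")


if __name__ == "__main__":
    main()
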