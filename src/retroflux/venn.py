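"""Deviation-from-average bookkeeping and Venn-region counts.

After per-spot standardization the grand mean of every profile is zero, so
"synthesized above or below the average of all treatments" reduces to a
threshold on the condition means of the z-scored profile. The quantitative
threshold is a pipeline choice (default 1.0 standardized unit), not a value
inherited from any gel study. Region counts decompose the per-condition
deviation sets by inclusion–exclusion so that each condition total equals
its specific count plus its overlap regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .fixtures import percent_of
from .matrix import parse_sample_name


@dataclass
class DeviationSet:
    """Spots deviating from the all-treatment average in one condition."""

    condition: str
    direction: dict  # spot_id -> "above" | "below"

    @property
    def members(self) -> frozenset:
        return frozenset(self.direction)

    def __len__(self) -> int:
        return len(self.direction)


def deviation_sets(standardized: pd.DataFrame, theta: float = 1.0) -> list[DeviationSet]:
    """Per-condition sets of spots whose mean z-score deviates by ≥ theta.

    A spot deviates in condition c iff |mean z over c's replicates| ≥ theta;
    the direction is the sign of that mean.
    """
    if theta <= 0:
        raise ConfigurationError(f"theta must be positive, got {theta}")
    by_cond: dict[str, list] = {}
    for col in standardized.columns:
        cond, _, _ = parse_sample_name(col)
        by_cond.setdefault(cond, []).append(col)
    sets = []
    for cond, cols in by_cond.items():
        means = standardized[cols].mean(axis=1)
        hits = means[means.abs() >= theta]
        direction = {sid: ("above" if v > 0 else "below") for sid, v in hits.items()}
        sets.append(DeviationSet(cond, direction))
    return sets


@dataclass
class VennReport:
    """Exact region decomposition of the deviation sets over a spot universe."""

    universe_size: int
    conditions: tuple
    totals: dict            # condition -> |set|
    region_counts: dict     # frozenset of conditions -> exclusive count
    percentages: dict       # condition -> integer percent of universe

    def specific(self, condition: str) -> int:
        return self.region_counts.get(frozenset([condition]), 0)

    def overlap(self, *conditions: str) -> int:
        """Spots in exactly this set of conditions (exclusive region)."""
        return self.region_counts.get(frozenset(conditions), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "+".join(sorted(key)), "n_conditions": len(key), "count": count}
            for key, count in sorted(self.region_counts.items(),
                                     key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["region", "n_conditions", "count"])


def venn_counts(sets: list[DeviationSet], universe_size: int,
                universe=None) -> VennReport:
    """Decompose up to four deviation sets into exclusive Venn regions.

    ``universe`` (optional collection of spot ids) enables the consistency
    check that every set member belongs to the significant-spot universe.
    Percentages are counts over ``universe_size``, rounded half away from zero.
    """
    if universe_size <= 0:
        raise ConfigurationError("universe_size must be positive")
    if universe is not None:
        universe = set(universe)
        for s in sets:
            stray = s.members - universe
            if stray:
                raise ConsistencyError(
                    f"spots outside the universe in condition {s.condition!r}: "
                    f"{sorted(map(str, stray))[:5]}")
    conditions = tuple(s.condition for s in sets)
    membership: dict = {}
    for s in sets:
        for sid in s.members:
            membership.setdefault(sid, set()).add(s.condition)
    region_counts: dict = {}
    for conds in membership.values():
        key = frozenset(conds)
        region_counts[key] = region_counts.get(key, 0) + 1
    totals = {s.condition: len(s) for s in sets}
    percentages = {c: percent_of(totals[c], universe_size) for c in conditions}
    return VennReport(universe_size, conditions, totals, region_counts, percentages)


def region_plot(report: VennReport, path) -> None:
    """UpSet-style bar chart of the exclusive Venn regions (4-set friendly)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = report.to_frame()
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(frame) + 2), 3.5))
    if len(frame):
        ax.bar(range(len(frame)), frame["count"], color="#4878a8")
        ax.set_xticks(range(len(frame)))
        ax.set_xticklabels(frame["region"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("spots in exclusive region")
    ax.set_title(f"deviation regions over {report.universe_size} significant spots")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report_tsv(report: VennReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# universe_size\t{report.universe_size}\n")
        fh.write("condition\ttotal\tspecific\tpercent_of_universe\n")
        for cond in report.conditions:
            fh.write(f"{cond}\t{report.totals[cond]}\t{report.specific(cond)}\t"
                     f"{report.percentages[cond]}\n")
        fh.write("\nregion\tn_conditions\tcount\n")
        for _, row in report.to_frame().iterrows():
            fh.write(f"{row['region']}\t{row['n_conditions']}\t{row['count']}\n")
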