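"""End-to-end pipeline: simulate (optional) → normalize → fold change →
ANOVA filter → archetype clustering → Venn bookkeeping → concordance →
report bundle.

The report directory contains tab-separated tables, the heat map, the
Venn-region plot, the concordance scatter, a three-level table (silver
change, de novo change, transcript change per feature and contrast) and a
plain-text summary. Given the same configuration and seed the tabular
outputs are byte-identical between runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import differential, venn
from .errors import PipelineError, RetrofluxError
from .matrix import SpotMatrix
from .normalize import (CONTRASTS, compute_log2fc, normalize_total,
                        read_foldchange_tsv, write_foldchange_tsv)
from .simulate import SimulationConfig, generate_experiment, write_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run on: either a simulation config or user-supplied tables."""

    simulation: SimulationConfig | None = None
    autoradiogram_path: str | None = None
    silver_path: str | None = None
    transcript_path: str | None = None
    alpha: float = 0.01
    k: int = 4
    theta: float = 1.0
    cutoff: float = 0.5
    perpendicular: bool = False
    na_sentinel: str = "NA"


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except RetrofluxError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(name, exc) from exc
    return wrap


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- inputs ---------------------------------------------------------
    if config.simulation is not None:
        try:
            experiment = generate_experiment(config.simulation)
            write_experiment(experiment, out / "simulated")
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc
        auto = experiment.autoradiogram
        silver = experiment.silver
        transcript_fc = experiment.transcript_fc
    else:
        if config.autoradiogram_path is None:
            raise PipelineError("input", ValueError("no autoradiogram matrix supplied"))
        auto = SpotMatrix.read_tsv(config.autoradiogram_path,
                                   na_sentinel=config.na_sentinel)
        silver = (SpotMatrix.read_tsv(config.silver_path,
                                      na_sentinel=config.na_sentinel)
                  if config.silver_path else None)
        transcript_fc = (read_foldchange_tsv(config.transcript_path)
                         if config.transcript_path else None)

    # --- normalize + fold changes --------------------------------------
    try:
        auto_norm = normalize_total(auto)
        fc_parts = [compute_log2fc(auto_norm, CONTRASTS)]
        if silver is not None:
            fc_parts.append(compute_log2fc(normalize_total(silver), CONTRASTS))
        if transcript_fc is not None:
            fc_parts.append(transcript_fc)
        fold_changes = pd.concat(fc_parts, ignore_index=True)
        auto_norm.write_tsv(out / "autoradiogram_normalized.tsv", config.na_sentinel)
        write_foldchange_tsv(fold_changes, out / "fold_changes.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    # --- significance filter + clustering ------------------------------
    try:
        anova = differential.anova_filter(auto_norm, alpha=config.alpha)
        anova.to_csv(out / "anova.tsv", sep="\t", na_rep=config.na_sentinel)
        significant = anova.index[anova["significant"]]
        summary["n_tested"] = len(anova)
        summary["n_significant"] = int(anova["significant"].sum())
        z = differential.standardize(auto_norm.data.loc[significant])
        if len(z) < config.k:
            raise RetrofluxError(
                f"only {len(z)} significant spots, cannot form {config.k} clusters")
        assignment = differential.hierarchical_cluster(z, k=config.k)
        assignment.assignments.to_csv(out / "clusters.tsv", sep="\t")
        differential.heatmap_export(z, assignment, out / "heatmap.png",
                                    out / "heatmap_matrix.tsv")
        summary["cluster_sizes"] = assignment.clusters.value_counts().sort_index().to_dict()
    except (PipelineError, RetrofluxError):
        raise
    except Exception as exc:
        raise PipelineError("cluster", exc) from exc

    # --- deviation sets and Venn regions --------------------------------
    try:
        sets = venn.deviation_sets(z, theta=config.theta)
        report = venn.venn_counts(sets, universe_size=len(z), universe=z.index)
        venn.write_report_tsv(report, out / "venn_report.tsv")
        venn.region_plot(report, out / "venn_regions.png")
        summary["venn_totals"] = report.totals
        summary["venn_percentages"] = report.percentages
    except RetrofluxError:
        raise
    except Exception as exc:
        raise PipelineError("venn", exc) from exc

    # --- concordance -----------------------------------------------------
    if transcript_fc is None:
        logger.warning("no transcript table: concordance stage skipped")
        summary["concordance"] = None
    else:
        try:
            table = conc.response_factor_table(fold_changes)
            table = conc.classify_concordance(table, cutoff=config.cutoff,
                                              perpendicular=config.perpendicular)
            table.to_csv(out / "response_factors.tsv", sep="\t")
            conc.plot_concordance(table, config.cutoff, out / "concordance.png")
            frac, n_disc, n_total = conc.translational_control_fraction(table)
            summary["concordance"] = {
                "fraction_discordant": frac,
                "n_discordant": n_disc,
                "n_features": n_total,
            }
        except RetrofluxError:
            raise
        except Exception as exc:
            raise PipelineError("concordance", exc) from exc

    # --- three-level comparison table -----------------------------------
    try:
        wide = fold_changes.pivot_table(index="feature_id",
                                        columns=["method", "contrast"],
                                        values="f_poi", aggfunc="first")
        wide.columns = [f"{m}|{c}" for m, c in wide.columns]
        wide.sort_index(axis=1).to_csv(out / "three_level_table.tsv", sep="\t",
                                       na_rep=config.na_sentinel)
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("retroflux pipeline summary\n")
        fh.write(f"spots tested\t{summary.get('n_tested')}\n")
        fh.write(f"significant (p ≤ {config.alpha})\t{summary.get('n_significant')}\n")
        for cl, size in summary.get("cluster_sizes", {}).items():
            fh.write(f"cluster {cl}\t{size}\n")
        for cond, total in summary.get("venn_totals", {}).items():
            fh.write(f"deviating in {cond}\t{total}\t"
                     f"{summary['venn_percentages'][cond]}%\n")
        if summary.get("concordance"):
            c = summary["concordance"]
            fh.write(f"discordant features\t{c['n_discordant']}/{c['n_features']}"
                     f"\t({c['fraction_discordant']:.3f})\n")
        elif summary.get("concordance") is None:
            fh.write("concordance\tskipped (no transcript table)\n")
    return summary
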