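"""Significance filtering and archetype clustering of spot profiles.

Spots whose intensity differs among the four treatments are found with a
classical one-way fixed-effects ANOVA (four groups of replicate gels; at
three replicates df1 = 3, df2 = 8) at a raw, uncorrected threshold
(default p ≤ 0.01; an optional Benjamini–Hochberg correction is available
but off by default). Significant profiles are z-scored per spot and grouped
by agglomerative clustering with euclidean distance and complete linkage,
cutting the tree at k clusters (default 4 regulation archetypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import ConfigurationError, RetrofluxError
from .matrix import SpotMatrix, CONDITIONS, parse_sample_name

logger = logging.getLogger(__name__)


def _anova_from_groups(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """One-way fixed-effects F test from a sum-of-squares decomposition.

    Returns (F, p, df1, df2). Zero between- and within-group variance is
    treated as no evidence (F = 0, p = 1); zero within-group variance with
    spread between groups gives p → 0.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n_total = int(ns.sum())
    df1, df2 = k - 1, n_total - k
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0, df1, df2
        return np.inf, 0.0, df1, df2
    f = (ssb / df1) / (ssw / df2)
    return f, float(stats.f.sf(f, df1, df2)), df1, df2


def anova_filter(normalized: SpotMatrix, alpha: float = 0.01,
                 bh_correct: bool = False) -> pd.DataFrame:
    """One-way ANOVA across conditions for every spot.

    Spots with missing gels are tested on the available data as long as at
    least two conditions retain data and the residual degrees of freedom are
    positive; otherwise they are excluded with a log entry. No
    multiple-testing correction is applied unless ``bh_correct`` is set.

    Returns a frame indexed by spot_id with F, p, per-condition means,
    df1, df2 and the significance call (p ≤ alpha).
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    conditions = normalized.conditions
    cols_by_cond = {c: normalized.columns_for(c) for c in conditions}
    records = []
    excluded = 0
    for spot_id, row in normalized.data.iterrows():
        groups = []
        for cond in conditions:
            vals = row[cols_by_cond[cond]].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                groups.append(vals)
        n_total = sum(len(g) for g in groups)
        if len(groups) < 2 or n_total - len(groups) < 1:
            excluded += 1
            continue
        f, p, df1, df2 = _anova_from_groups(groups)
        means = {f"mean_{c}": (np.nanmean(row[cols_by_cond[c]].to_numpy(float))
                               if not np.all(np.isnan(row[cols_by_cond[c]].to_numpy(float)))
                               else np.nan)
                 for c in conditions}
        records.append({"spot_id": spot_id, "F": f, "p": p,
                        "df1": df1, "df2": df2, **means})
    if excluded:
        logger.info("excluded %d spots with insufficient data for ANOVA", excluded)
    result = pd.DataFrame(records).set_index("spot_id")
    if bh_correct and len(result):
        order = np.argsort(result["p"].to_numpy())
        m = len(result)
        q = np.empty(m)
        ranked = result["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        result["p_adjusted"] = np.minimum(q, 1.0)
        result["significant"] = result["p_adjusted"] <= alpha
    else:
        result["significant"] = result["p"] <= alpha
    return result


def standardize(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score each spot's profile across its samples.

    ``ddof=1`` (sample SD) is the shipped default; ``ddof=0`` switches to the
    population SD. Zero-variance spots cannot be standardized and are dropped
    with a log entry.
    """
    values = profiles.to_numpy(float)
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    if (~keep).any():
        logger.info("excluded %d zero-variance spots from standardization",
                    int((~keep).sum()))
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=profiles.index[keep], columns=profiles.columns)


@dataclass
class ClusterAssignment:
    """Cluster labels plus the dendrogram needed to reproduce the heat map."""

    assignments: pd.DataFrame  # index spot_id, columns: cluster
    leaf_order: list = field(repr=False)
    linkage: np.ndarray = field(repr=False)

    @property
    def clusters(self) -> pd.Series:
        return self.assignments["cluster"]


def hierarchical_cluster(standardized: pd.DataFrame, k: int = 4) -> ClusterAssignment:
    """Agglomerative clustering (euclidean, complete linkage), tree cut at k.

    Cluster labels 1..k are assigned in order of first appearance along the
    dendrogram leaves, so the labelling is deterministic given the input
    order (ties in the agglomeration are broken by scipy's deterministic
    pair ordering).
    """
    n = len(standardized)
    if k > n:
        raise ConfigurationError(f"cannot cut {n} spots into {k} clusters")
    if k < 1:
        raise ConfigurationError("k must be at least 1")
    values = standardized.to_numpy(float)
    if n == 1:
        return ClusterAssignment(
            pd.DataFrame({"cluster": [1]}, index=standardized.index), [0],
            np.empty((0, 4)))
    link = hierarchy.linkage(values, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise RetrofluxError(
            f"tree cut produced {len(np.unique(raw))} clusters instead of {k} "
            "(duplicate profiles?)")
    leaves = hierarchy.leaves_list(link).tolist()
    relabel: dict[int, int] = {}
    for leaf in leaves:
        relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
    clusters = [relabel[int(c)] for c in raw]
    assignments = pd.DataFrame({"cluster": clusters}, index=standardized.index)
    return ClusterAssignment(assignments, leaves, link)


def order_matrix(standardized: pd.DataFrame, assignment: ClusterAssignment,
                 condition_order: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Rows in dendrogram-leaf order, replicate gels grouped by condition."""
    col_key = []
    for i, col in enumerate(standardized.columns):
        cond, rep, _ = parse_sample_name(col)
        rank = condition_order.index(cond) if cond in condition_order else len(condition_order)
        col_key.append((rank, rep, i))
    cols = [standardized.columns[i] for _, _, i in sorted(col_key)]
    rows = [standardized.index[i] for i in assignment.leaf_order]
    return standardized.loc[rows, cols]


def heatmap_export(standardized: pd.DataFrame, assignment: ClusterAssignment,
                   image_path, table_path,
                   condition_order: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Write the clustered heat map (raster) and the underlying ordered matrix."""
    if standardized.empty:
        raise RetrofluxError("no significant spots: nothing to export")
    ordered = order_matrix(standardized, assignment, condition_order)
    ordered_out = ordered.copy()
    ordered_out.insert(0, "cluster",
                       assignment.assignments.loc[ordered.index, "cluster"])
    ordered_out.to_csv(table_path, sep="\t", index_label="spot_id")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(3, 0.04 * len(ordered) + 2)))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5, interpolation="nearest")
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(ordered)} spots (dendrogram order)")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    return ordered_out
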