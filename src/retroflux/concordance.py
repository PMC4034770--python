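"""The response-factor statistic R and the transcript/translation concordance call.

For each measurement method (transcript regulation, de novo protein
synthesis) and each of the two high-light shift contrasts (N→H/N, L→H/L),
every feature's log2 fold change F_POI is scaled by the extreme reaction
F_Ext of its own sign observed in the analysed feature set: up-regulated
values are divided by the maximum positive fold change, down-regulated
values by the magnitude of the maximal negative fold change. Each scaled
value lies in [-1, 1]; the per-method sum over the two shift contrasts is
the response factor R ∈ [-2, 2] (+2 = maximal up-regulation in both shifts,
-2 = maximal down-regulation in both).

Transcript and translation regulation are called concordant when the point
(R_transcript, R_de_novo) falls inside a band of half-width ``cutoff``
(default 0.5) around the diagonal, measured as the coordinate difference
d = |R_de_novo - R_transcript| (the boundary d = cutoff is concordant);
``perpendicular=True`` uses the euclidean distance to the diagonal, d/√2,
instead. The extreme is always taken over the feature set actually supplied:
the analysis universe is an explicit input, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RetrofluxError
from .normalize import H_CONTRASTS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtremeSet:
    """Per (contrast, sign) extreme fold changes F_Ext for one method."""

    method: str
    positive: dict  # contrast -> max positive F_POI (or None if no positive values)
    negative: dict  # contrast -> min negative F_POI (or None if no negative values)


def extreme_normalize(fc: pd.DataFrame, method: str,
                      contrasts: tuple[str, ...] = H_CONTRASTS
                      ) -> tuple[pd.DataFrame, ExtremeSet]:
    """Scale each F_POI by the extreme reaction of its sign, preserving sign.

    Returns the long table restricted to ``method`` and ``contrasts`` with an
    added column ``v`` in [-1, 1] (F_POI = 0 maps to v = 0), plus the
    extremes used.
    """
    sub = fc[(fc["method"] == method) & fc["contrast"].isin(contrasts)].copy()
    sub = sub[~sub["f_poi"].isna()]
    if sub.empty:
        raise RetrofluxError(f"no fold changes for method {method!r}")
    positive: dict = {}
    negative: dict = {}
    v = np.zeros(len(sub))
    values = sub["f_poi"].to_numpy(float)
    for contrast in contrasts:
        mask = (sub["contrast"] == contrast).to_numpy()
        vals = values[mask]
        pos = vals[vals > 0]
        neg = vals[vals < 0]
        positive[contrast] = float(pos.max()) if len(pos) else None
        negative[contrast] = float(neg.min()) if len(neg) else None
        out = np.zeros(len(vals))
        up = vals > 0
        down = vals < 0
        # zero/undefined extremes alongside nonzero values of that sign cannot
        # occur: the extreme is the max/min over those very values
        assert not (up.any() and positive[contrast] is None)
        assert not (down.any() and negative[contrast] is None)
        if up.any():
            out[up] = vals[up] / positive[contrast]
        if down.any():
            out[down] = vals[down] / abs(negative[contrast])
        v[mask] = out
    sub["v"] = v
    return sub, ExtremeSet(method, positive, negative)


def response_factor(normalized: pd.DataFrame,
                    contrasts: tuple[str, ...] = H_CONTRASTS) -> pd.Series:
    """R = sum of the extreme-normalized values over the shift contrasts.

    Features missing one of the contrasts are skipped with a log entry.
    """
    wide = normalized.pivot_table(index="feature_id", columns="contrast",
                                  values="v", aggfunc="first")
    missing = [c for c in contrasts if c not in wide.columns]
    if missing:
        raise RetrofluxError(f"contrast(s) {missing} absent from normalized table")
    complete = wide[list(contrasts)].dropna()
    skipped = len(wide) - len(complete)
    if skipped:
        logger.info("skipped %d features missing a shift contrast", skipped)
    return complete.sum(axis=1).rename("R")


def response_factor_table(fc: pd.DataFrame,
                          contrasts: tuple[str, ...] = H_CONTRASTS,
                          transcript_method: str = "transcript",
                          de_novo_method: str = "de_novo") -> pd.DataFrame:
    """Per-feature R for both methods (features quantified in both are kept)."""
    norm_t, _ = extreme_normalize(fc, transcript_method, contrasts)
    norm_p, _ = extreme_normalize(fc, de_novo_method, contrasts)
    r_t = response_factor(norm_t, contrasts)
    r_p = response_factor(norm_p, contrasts)
    table = pd.DataFrame({"R_transcript": r_t, "R_de_novo": r_p}).dropna()
    table.index.name = "feature_id"
    return table


def classify_concordance(table: pd.DataFrame, cutoff: float = 0.5,
                         perpendicular: bool = False) -> pd.DataFrame:
    """Add the diagonal deviation d and the concordant/discordant call.

    The call is discordant iff d > cutoff (a deviation exactly at the cutoff
    still counts as concordant).
    """
    if cutoff < 0:
        raise ConfigurationError(f"cutoff must be non-negative, got {cutoff}")
    out = table.copy()
    d = (out["R_de_novo"] - out["R_transcript"]).abs()
    if perpendicular:
        d = d / np.sqrt(2.0)
    out["deviation"] = d
    out["call"] = np.where(d > cutoff, "discordant", "concordant")
    return out


def translational_control_fraction(table: pd.DataFrame) -> tuple[float, int, int]:
    """Fraction of features whose translation is decoupled from the transcript.

    Returns (fraction, n_discordant, n_total).
    """
    if table.empty:
        raise RetrofluxError("empty response-factor table")
    if "call" not in table.columns:
        raise RetrofluxError("concordance calls missing; run classify_concordance first")
    n_total = len(table)
    n_disc = int((table["call"] == "discordant").sum())
    return n_disc / n_total, n_disc, n_total


def plot_concordance(table: pd.DataFrame, cutoff: float, path,
                     label_features: bool = False) -> None:
    """Scatter of R_de_novo vs R_transcript with the diagonal concordance band."""
    if table.empty:
        raise RetrofluxError("empty response-factor table")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    span = np.array([-2.2, 2.2])
    ax.fill_between(span, span - cutoff, span + cutoff,
                    color="0.85", zorder=0, label=f"|d| ≤ {cutoff}")
    ax.plot(span, span, color="0.5", lw=0.8, zorder=1)
    colors = table.get("call", pd.Series("concordant", index=table.index)).map(
        {"concordant": "#33679b", "discordant": "#c23b22"})
    ax.scatter(table["R_transcript"], table["R_de_novo"], s=18, c=colors, zorder=2)
    if label_features:
        for fid, row in table.iterrows():
            ax.annotate(str(fid), (row["R_transcript"], row["R_de_novo"]),
                        fontsize=5, xytext=(2, 2), textcoords="offset points")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_xlabel("R (transcript regulation)")
    ax.set_ylabel("R (de novo protein synthesis)")
    ax.set_title("response-factor concordance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
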