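"""Per-gel total-intensity normalization and log2 fold changes.

Gels are loaded with a fixed amount of protein or radiolabel, so spot
quantities are only comparable as shares of their gel's total intensity.
:func:`normalize_total` converts each gel column to such shares;
:func:`compute_log2fc` turns condition means of the shares into per-contrast
log2 fold changes (one row per feature × method × contrast, long format).

Note the compositional consequence of total normalization: a spot that takes
up a share ``s`` of one condition's gels (a dominant RubisCO-like spot)
depresses every other spot's share there by the factor ``1 - s``, shifting
their apparent log2 fold change in contrasts against that condition by
``log2(1 - s)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import NormalizationError, ConfigurationError
from .matrix import SpotMatrix

logger = logging.getLogger(__name__)

#: Treatment contrasts, written numerator/denominator. The two light-shift
#: contrasts compare each high-light treatment with its own acclimation state.
CONTRASTS = ("N/L", "N→H/N", "L→H/L", "L→H/N→H")

#: The two high-light shift contrasts entering the response factor.
H_CONTRASTS = ("N→H/N", "L→H/L")


def parse_contrast(contrast: str) -> tuple[str, str]:
    parts = contrast.split("/")
    if len(parts) != 2 or not all(parts):
        raise ConfigurationError(f"contrast {contrast!r} is not 'numerator/denominator'")
    return parts[0], parts[1]


def normalize_total(matrix: SpotMatrix) -> SpotMatrix:
    """Divide every spot by its gel's total intensity (missing values propagate).

    Raises :class:`NormalizationError` naming the sample if a gel has no
    positive intensity.
    """
    totals = matrix.data.sum(axis=0, skipna=True)
    bad = totals[(totals <= 0) | totals.isna()]
    if len(bad):
        raise NormalizationError(
            f"gel(s) with non-positive total intensity: {', '.join(map(str, bad.index))}"
        )
    return SpotMatrix(matrix.data.div(totals, axis=1), matrix.channel)


def compute_log2fc(
    normalized: SpotMatrix,
    contrasts: tuple[str, ...] = CONTRASTS,
    method: str | None = None,
) -> pd.DataFrame:
    """Per-spot log2(mean numerator / mean denominator) for each contrast.

    Replicates are averaged per condition before the ratio is taken
    (ratio of means, robust to single-replicate dropouts in raw data).
    A spot missing (ND) in any replicate of a required condition is flagged
    ``nd`` with an undefined fold change. Ratios with a zero numerator or
    denominator mean are excluded with a logged count.

    Returns a long-format frame: feature_id, method, contrast, f_poi, nd.
    """
    method = method or normalized.method
    cond_means = normalized.condition_means()
    rows = []
    n_undefined = 0
    for contrast in contrasts:
        num, den = parse_contrast(contrast)
        for cond in (num, den):
            if cond not in cond_means.columns:
                raise ConfigurationError(
                    f"contrast {contrast!r} needs condition {cond!r}, absent from matrix"
                )
        a = cond_means[num].to_numpy(float)
        b = cond_means[den].to_numpy(float)
        nd = np.isnan(a) | np.isnan(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.log2(a / b)
        undefined = ~nd & ~np.isfinite(fc)
        n_undefined += int(undefined.sum())
        for fid, f, is_nd, is_undef in zip(cond_means.index, fc, nd, undefined):
            if is_undef:
                continue
            rows.append((fid, method, contrast, np.nan if is_nd else float(f), bool(is_nd)))
    if n_undefined:
        logger.warning("excluded %d fold changes with zero condition means", n_undefined)
    return pd.DataFrame(rows, columns=["feature_id", "method", "contrast", "f_poi", "nd"])


def read_foldchange_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    required = {"feature_id", "method", "contrast", "f_poi"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"fold-change table misses columns {sorted(missing)}")
    if "nd" not in df.columns:
        df["nd"] = df["f_poi"].isna()
    df["nd"] = df["nd"].astype(bool)
    return df


def write_foldchange_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
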