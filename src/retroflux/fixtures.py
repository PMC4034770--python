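"""Packaged reference tables and the small derived statistics printed from them.

Three tab-separated fixtures ship with the package:

* ``table1_physiology.tsv`` — treatment means ± SD for chlorophyll, ΦPSII,
  protein and RNA in the four light treatments (N, N→H, L, L→H).
* ``table2_proteins.tsv`` — the 49 polypeptides identified on both the
  silver-stained gels and the autoradiograms, with localization, functional
  role, detection flags and Mascot score.
* ``table3_clusters.tsv`` — the archetype catalog assigning identified
  proteins to the four regulation clusters (plus the no-pattern remainder).

All percent arithmetic uses half-away-from-zero integer rounding, the
convention every printed percentage in the study follows.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .errors import ConfigurationError, RetrofluxError


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (unlike banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_of(count: float, universe: float) -> int:
    """100·count/universe as an integer percent (half away from zero)."""
    if universe == 0:
        raise ConfigurationError("cannot take a percentage of an empty universe")
    return round_half_away(100.0 * count / universe)


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("retroflux.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_physiology() -> pd.DataFrame:
    """Treatment physiology: parameter, unit, treatment, mean, sd, significance."""
    df = _read_fixture("table1_physiology.tsv")
    if len(df) != 16:
        raise RetrofluxError(f"physiology fixture has {len(df)} records, expected 16")
    if (df["mean"] <= 0).any() or (df["sd"] < 0).any():
        raise RetrofluxError("physiology fixture violates mean > 0 / sd ≥ 0")
    return df


def load_proteins() -> pd.DataFrame:
    """The 49 identified polypeptides with detection flags and annotation."""
    df = _read_fixture("table2_proteins.tsv")
    for i, row in df.iterrows():
        atg = str(row["atg"])
        if not (len(atg) == 9 and atg.startswith("AT")
                and (atg[2].isdigit() or atg[2] == "C") and atg[3] == "G"
                and atg[4:].isdigit()):
            raise RetrofluxError(f"line {i + 2}: malformed ATG accession {atg!r}")
        if row["de_novo"] not in {"+", "ND"}:
            raise RetrofluxError(f"line {i + 2}: unknown de novo flag {row['de_novo']!r}")
        if not (isinstance(row["mascot_score"], (int,)) or float(row["mascot_score"]).is_integer()) \
                or row["mascot_score"] <= 0:
            raise RetrofluxError(f"line {i + 2}: Mascot score must be a positive integer")
    return df


def load_cluster_catalog() -> pd.DataFrame:
    """Archetype membership of the identified proteins (literal names preserved)."""
    return _read_fixture("table3_clusters.tsv")


def ratio_to_reference(physiology: pd.DataFrame, parameter: str,
                       numerator: str, denominator: str) -> int:
    """Integer percent of one treatment's mean relative to another's."""
    sub = physiology[physiology["parameter"] == parameter].set_index("treatment")
    for t in (numerator, denominator):
        if t not in sub.index:
            raise ConfigurationError(f"treatment {t!r} absent for parameter {parameter!r}")
    den = sub.loc[denominator, "mean"]
    if den == 0:
        raise ConfigurationError("zero denominator mean")
    return percent_of(sub.loc[numerator, "mean"], den)


def count_records(proteins: pd.DataFrame) -> int:
    return len(proteins)


def count_not_detected(proteins: pd.DataFrame) -> int:
    """Proteins present on silver gels but absent from the autoradiograms."""
    silver_detected = proteins["silver"].astype(str).str.contains(r"\+")
    return int(((proteins["de_novo"] == "ND") & silver_detected).sum())


def fraction_localized(proteins: pd.DataFrame, compartment: str) -> int:
    """Integer percent of proteins whose localization names the compartment.

    Dual localizations ("Chloro/Mito") count as matches for either
    compartment; matching is case-insensitive on the compartment prefix.
    """
    if proteins.empty:
        raise ConfigurationError("empty protein fixture")
    comp = compartment.lower()

    def matches(localization: str) -> bool:
        tokens = [t.strip(". ").lower() for t in str(localization).split("/")]
        return any(len(t) >= 4 and (t.startswith(comp) or comp.startswith(t))
                   for t in tokens)

    hits = proteins["localization"].map(matches)
    return percent_of(int(hits.sum()), len(proteins))
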