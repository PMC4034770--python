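"""Synthetic 2D-gel / autoradiogram experiments with known ground truth.

The generator emulates the four-condition (L, L→H, N, N→H) × three-replicate
gel design: every spot gets a lognormal baseline abundance, a regulation
archetype drawn from the four cluster patterns (plus a no-pattern remainder),
multiplicative replicate noise on the log2 scale, an optional dominant
RubisCO-like spot carrying a fixed share of the total intensity in the N and
N→H gels, optional not-detected (ND) dropout in the autoradiogram channel,
and a planted fraction of features whose de novo synthesis is decoupled from
their transcript regulation.

Archetype condition patterns (log2 offsets, in units of ``effect_size``),
in the order (L, L→H, N, N→H):

=========  ==================================  ==================
archetype  meaning                             pattern
=========  ==================================  ==================
1          synthesis low in both H shifts      (0, -1, 0, -1)
2          synthesis high in both H shifts     (0, +1, 0, +1)
3          up in N→H, down in L→H              (0, -1, 0, +1)
4          N and N→H high vs L and L→H low     (0,  0, +1, +1)
none       no peculiar pattern                 (0,  0,  0,  0)
=========  ==================================  ==================

Ground-truth effects are recorded on the *relative* (total-normalized) scale
the pipeline actually measures: planting archetype effects changes each
gel's total intensity, so every spot's true relative fold change carries a
common per-contrast closure shift δ = log2 of the ratio of noise-free gel
totals. With zero replicate noise the quantify/normalize stage therefore
reproduces the recorded true effects exactly once the dominant spot is
removed; with the dominant spot present, contrasts against the N conditions
are additionally shifted by log2(1 - dominant share) — the compositional
distortion total normalization is known for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import SpotMatrix, CONDITIONS, sample_name
from .normalize import CONTRASTS, H_CONTRASTS, parse_contrast
from . import concordance as _concordance

ARCHETYPES = ("1", "2", "3", "4", "none")

ARCHETYPE_PATTERNS = {
    "1": np.array([0.0, -1.0, 0.0, -1.0]),
    "2": np.array([0.0, 1.0, 0.0, 1.0]),
    "3": np.array([0.0, -1.0, 0.0, 1.0]),
    "4": np.array([0.0, 0.0, 1.0, 1.0]),
    "none": np.array([0.0, 0.0, 0.0, 0.0]),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated light-shift experiment.

    Defaults emulate the real design: 129 reliably detected spots, three
    replicate gels per treatment, archetype proportions matching the
    identified-protein catalog (8:8:10:8 in clusters 1–4 plus 14 without a
    peculiar pattern), 2 log2-unit archetype effects, a RubisCO-like spot
    holding 30% of the N/N→H gel intensity, an 8/49 autoradiogram dropout
    rate and almost two thirds of features with transcript-decoupled
    synthesis.
    """

    n_spots: int = 129
    n_replicates: int = 3
    conditions: tuple = CONDITIONS
    archetype_proportions: tuple = (8 / 48, 8 / 48, 10 / 48, 8 / 48, 14 / 48)
    effect_size: float = 2.0
    noise_sd: float = 0.25
    dominant_spot_share: float = 0.30
    nd_dropout_rate: float = 8 / 49
    discordance_fraction: float = 0.65
    discordance_mode: str = "flip"  # or "zero"
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    na_sentinel: str = "NA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ConfigurationError("n_spots must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        props = np.asarray(self.archetype_proportions, float)
        if len(props) != len(ARCHETYPES):
            raise ConfigurationError(
                f"archetype_proportions needs {len(ARCHETYPES)} weights")
        if (props < 0).any():
            raise ConfigurationError("archetype proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype proportions sum to {props.sum()}, not 1")
        for name in ("dominant_spot_share", "nd_dropout_rate", "discordance_fraction"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0 or (name == "dominant_spot_share" and rate >= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {rate}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.discordance_mode not in {"flip", "zero"}:
            raise ConfigurationError(
                f"unknown discordance_mode {self.discordance_mode!r}")
        n_requested = int((props > 0).sum())
        if self.n_spots < n_requested:
            raise ConfigurationError(
                f"{self.n_spots} spots cannot host {n_requested} archetype classes")

    def to_text(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key}:{value}\n")

    @classmethod
    def from_text(cls, path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, value = line.split(":", 1)
                kwargs[key] = value
        return cls(
            n_spots=int(kwargs["n_spots"]),
            n_replicates=int(kwargs["n_replicates"]),
            conditions=tuple(kwargs["conditions"].split(",")),
            archetype_proportions=tuple(float(x) for x in
                                        kwargs["archetype_proportions"].split(",")),
            effect_size=float(kwargs["effect_size"]),
            noise_sd=float(kwargs["noise_sd"]),
            dominant_spot_share=float(kwargs["dominant_spot_share"]),
            nd_dropout_rate=float(kwargs["nd_dropout_rate"]),
            discordance_fraction=float(kwargs["discordance_fraction"]),
            discordance_mode=kwargs["discordance_mode"],
            baseline_log2_mean=float(kwargs["baseline_log2_mean"]),
            baseline_log2_sd=float(kwargs["baseline_log2_sd"]),
            na_sentinel=kwargs["na_sentinel"],
            seed=int(kwargs["seed"]),
        )


@dataclass
class Experiment:
    """One simulated experiment: both gel channels, transcript table, truth."""

    autoradiogram: SpotMatrix
    silver: SpotMatrix
    transcript_fc: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig = field(repr=False)


def _contrast_indices(conditions: tuple, contrast: str) -> tuple[int, int]:
    num, den = parse_contrast(contrast)
    return conditions.index(num), conditions.index(den)


def _truth_concordance(truth: pd.DataFrame) -> pd.Series:
    """Concordant flag from the true effects, using the pipeline's own statistic."""
    rows = []
    for contrast in H_CONTRASTS:
        for method in ("transcript", "de_novo"):
            col = f"true_{method}_{contrast}"
            for fid, val in truth[col].items():
                rows.append((fid, method, contrast, val, False))
    fc = pd.DataFrame(rows, columns=["feature_id", "method", "contrast", "f_poi", "nd"])
    table = _concordance.response_factor_table(fc)
    table = _concordance.classify_concordance(table)
    return (table["call"] == "concordant").reindex(truth.index)


def generate_experiment(config: SimulationConfig) -> Experiment:
    """Draw one experiment; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_spots
    conds = tuple(config.conditions)
    n_cond = len(conds)
    reps = config.n_replicates
    e = config.effect_size

    width = max(4, len(str(n)))
    spot_ids = pd.Index([f"spot_{i + 1:0{width}d}" for i in range(n)], name="spot_id")

    archetypes = rng.choice(ARCHETYPES, size=n,
                            p=np.asarray(config.archetype_proportions, float))
    dominant_idx = 0 if config.dominant_spot_share > 0 else None
    if dominant_idx is not None:
        archetypes[dominant_idx] = "none"

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    pattern = np.stack([ARCHETYPE_PATTERNS[a] for a in archetypes])  # (n, 4)
    transcript_offsets = e * pattern
    denovo_offsets = transcript_offsets.copy()

    # decouple de novo synthesis from the transcript for a planted fraction:
    # flip (or zero) both H-shift effects; when the flip leaves the summed
    # response unchanged (R_t = 0 patterns) draw a fresh same-sign effect pair
    eligible = np.array([i for i in range(n) if i != dominant_idx])
    n_disc = int(round(config.discordance_fraction * len(eligible)))
    disc_idx = rng.choice(eligible, size=n_disc, replace=False) if n_disc else np.array([], int)
    discordant = np.zeros(n, bool)
    discordant[disc_idx] = True
    i_l, i_lh = conds.index("L"), conds.index("L→H")
    i_n, i_nh = conds.index("N"), conds.index("N→H")
    for i in disc_idx:
        t_lh = transcript_offsets[i, i_lh] - transcript_offsets[i, i_l]
        t_nh = transcript_offsets[i, i_nh] - transcript_offsets[i, i_n]
        if t_lh + t_nh != 0.0:
            new_lh, new_nh = ((-t_lh, -t_nh) if config.discordance_mode == "flip"
                              else (0.0, 0.0))
        else:
            sign = rng.choice([-1.0, 1.0])
            new_lh, new_nh = sign * e, sign * e
        denovo_offsets[i, i_lh] = denovo_offsets[i, i_l] + new_lh
        denovo_offsets[i, i_nh] = denovo_offsets[i, i_n] + new_nh

    # noise-free weights and closure shifts (dominant spot excluded)
    weights = 2.0 ** (baseline[:, None] + denovo_offsets)  # (n, n_cond)
    nondom = np.ones(n, bool)
    if dominant_idx is not None:
        nondom[dominant_idx] = False
    totals = weights[nondom].sum(axis=0)  # per condition
    delta = {}
    for contrast in CONTRASTS:
        ia, ib = _contrast_indices(conds, contrast)
        delta[contrast] = float(np.log2(totals[ib] / totals[ia]))

    truth = pd.DataFrame(index=spot_ids)
    truth["archetype"] = archetypes
    truth["dominant"] = [i == dominant_idx for i in range(n)]
    truth["planted_discordant"] = discordant
    for contrast in CONTRASTS:
        ia, ib = _contrast_indices(conds, contrast)
        truth[f"true_de_novo_{contrast}"] = (
            denovo_offsets[:, ia] - denovo_offsets[:, ib] + delta[contrast])
        truth[f"true_transcript_{contrast}"] = (
            transcript_offsets[:, ia] - transcript_offsets[:, ib] + delta[contrast])

    def gel_channel(offsets: np.ndarray) -> pd.DataFrame:
        cols = {}
        for ci, cond in enumerate(conds):
            for r in range(1, reps + 1):
                noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
                cols[(cond, r)] = 2.0 ** (baseline + offsets[:, ci] + noise)
        return pd.DataFrame(cols, index=spot_ids)

    def boost_dominant(frame: pd.DataFrame) -> None:
        # the RubisCO-like spot takes an exact share of the *detected* total
        # in every N and N→H gel
        s = config.dominant_spot_share
        for (cond, _r), col in frame.items():
            if cond in ("N", "N→H"):
                others = col.drop(spot_ids[dominant_idx]).sum()
                frame.loc[spot_ids[dominant_idx], (cond, _r)] = s / (1 - s) * others

    auto_frame = gel_channel(denovo_offsets)
    silver_frame = gel_channel(np.zeros_like(denovo_offsets))

    # ND dropout: a spot not detected in the autoradiogram channel at all
    # (applied before the dominant boost so the share is over detected spots)
    nd = np.zeros(n, bool)
    if config.nd_dropout_rate > 0:
        nd[nondom] = rng.random(int(nondom.sum())) < config.nd_dropout_rate
        auto_frame.loc[nd] = np.nan
    truth["nd"] = nd
    if dominant_idx is not None:
        boost_dominant(auto_frame)
        boost_dominant(silver_frame)

    # transcript log2 fold changes: true effects plus the standard error of a
    # replicate mean (noise_sd / sqrt(n_replicates)); exact at noise_sd = 0
    t_sd = config.noise_sd / np.sqrt(reps)
    rows = []
    for contrast in CONTRASTS:
        vals = truth[f"true_transcript_{contrast}"].to_numpy().copy()
        if t_sd > 0:
            vals = vals + rng.normal(0.0, t_sd, n)
        for fid, v in zip(spot_ids, vals):
            rows.append((fid, "transcript", contrast, float(v), False))
    transcript_fc = pd.DataFrame(
        rows, columns=["feature_id", "method", "contrast", "f_poi", "nd"])

    truth["concordant"] = _truth_concordance(truth).to_numpy()

    def to_matrix(frame: pd.DataFrame, channel: str) -> SpotMatrix:
        frame = frame.copy()
        frame.columns = [sample_name(c, r, channel) for c, r in frame.columns]
        return SpotMatrix(frame, channel)

    return Experiment(to_matrix(auto_frame, "autoradiogram"),
                      to_matrix(silver_frame, "silver"),
                      transcript_fc, truth, config)


def write_experiment(experiment: Experiment, out_dir) -> dict:
    """Write the experiment as tab-separated text; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sentinel = experiment.config.na_sentinel
    paths = {
        "autoradiogram": out / "autoradiogram_spots.tsv",
        "silver": out / "silver_spots.tsv",
        "transcript": out / "transcript_log2fc.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "config": out / "config.txt",
    }
    experiment.autoradiogram.write_tsv(paths["autoradiogram"], sentinel)
    experiment.silver.write_tsv(paths["silver"], sentinel)
    experiment.transcript_fc.to_csv(paths["transcript"], sep="\t", index=False,
                                    na_rep=sentinel)
    experiment.ground_truth.to_csv(paths["ground_truth"], sep="\t", na_rep=sentinel)
    experiment.config.to_text(paths["config"])
    return paths


# --- reference configurations for the calibration properties -----------------

def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-emulating condition (see class docstring)."""
    return replace(SimulationConfig(seed=seed), **overrides)


def null_config(n_spots: int = 2000, noise_sd: float = 0.25,
                seed: int = 0) -> SimulationConfig:
    """A pure null: no archetype effects, no dominant spot, no dropout.

    A dominant spot boosted in the N gels is itself a planted condition
    effect, so a type-I-error calibration must exclude it.
    """
    return SimulationConfig(
        n_spots=n_spots, archetype_proportions=(0, 0, 0, 0, 1),
        noise_sd=noise_sd, dominant_spot_share=0.0, nd_dropout_rate=0.0,
        discordance_fraction=0.0, seed=seed)


def archetype_recovery_config(n_spots: int = 400, effect_size: float = 2.0,
                              noise_sd: float = 0.25, seed: int = 0) -> SimulationConfig:
    """Four balanced planted archetypes with the nuisance processes disabled,
    isolating the clustering-recovery question."""
    return SimulationConfig(
        n_spots=n_spots, archetype_proportions=(0.25, 0.25, 0.25, 0.25, 0.0),
        effect_size=effect_size, noise_sd=noise_sd, dominant_spot_share=0.0,
        nd_dropout_rate=0.0, discordance_fraction=0.0, seed=seed)


def discordance_recovery_config(n_spots: int = 200, fraction: float = 0.65,
                                noise_sd: float = 0.1, seed: int = 0) -> SimulationConfig:
    """Planted transcript/translation decoupling at low noise, nuisance
    processes disabled, for parameter-recovery checks."""
    return SimulationConfig(
        n_spots=n_spots, discordance_fraction=fraction, noise_sd=noise_sd,
        dominant_spot_share=0.0, nd_dropout_rate=0.0, seed=seed)
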