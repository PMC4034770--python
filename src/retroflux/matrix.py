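"""Spot-intensity matrices from 2D-gel densitometry.

A :class:`SpotMatrix` holds one channel (silver densitometry or autoradiogram
greyness) of a spots × samples table. Samples are the individual gels of a
four-condition × n-replicate light-shift design; sample columns are named
``<condition>_<replicate>_<channel>`` so the metadata round-trips through
plain tab-separated text. Missing values mark spots not detected (ND) on a
gel; they are carried as NaN in memory and as a configurable sentinel
(default ``NA``) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Canonical treatment order: low light, low→high shift, normal light, normal→high shift.
CONDITIONS = ("L", "L→H", "N", "N→H")

#: Channel names and the measurement method they quantify.
CHANNEL_METHODS = {"autoradiogram": "de_novo", "silver": "silver"}


def sample_name(condition: str, replicate: int, channel: str) -> str:
    return f"{condition}_{replicate}_{channel}"


def parse_sample_name(name: str) -> tuple[str, int, str]:
    """Split ``<condition>_<replicate>_<channel>`` (conditions contain no ``_``)."""
    try:
        condition, replicate, channel = name.rsplit("_", 2)
        return condition, int(replicate), channel
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse sample name {name!r}") from exc


@dataclass
class SpotMatrix:
    """One channel of spot intensities with sample metadata in the column names."""

    data: pd.DataFrame  # index: spot_id, columns: sample names
    channel: str

    def __post_init__(self) -> None:
        for col in self.data.columns:
            _, _, channel = parse_sample_name(col)
            if channel != self.channel:
                raise ConfigurationError(
                    f"column {col!r} does not belong to channel {self.channel!r}"
                )
        if (self.data < 0).any().any():
            raise ConfigurationError("negative spot intensities are not allowed")

    @property
    def samples(self) -> pd.DataFrame:
        rows = [parse_sample_name(c) for c in self.data.columns]
        return pd.DataFrame(rows, columns=["condition", "replicate", "channel"],
                            index=pd.Index(self.data.columns, name="sample"))

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data.columns:
            seen.setdefault(parse_sample_name(c)[0])
        return list(seen)

    def columns_for(self, condition: str) -> list[str]:
        return [c for c in self.data.columns if parse_sample_name(c)[0] == condition]

    @property
    def method(self) -> str:
        """Measurement method quantified by this channel."""
        return CHANNEL_METHODS.get(self.channel, self.channel)

    def write_tsv(self, path, na_sentinel: str = "NA") -> None:
        self.data.to_csv(path, sep="\t", na_rep=na_sentinel, index_label="spot_id")

    @classmethod
    def read_tsv(cls, path, channel: str | None = None, na_sentinel: str = "NA") -> "SpotMatrix":
        df = pd.read_csv(path, sep="\t", index_col="spot_id",
                         na_values=[na_sentinel], keep_default_na=False)
        df = df.astype(float)
        if channel is None:
            channels = {parse_sample_name(c)[2] for c in df.columns}
            if len(channels) != 1:
                raise ConfigurationError(f"matrix mixes channels {sorted(channels)}")
            channel = channels.pop()
        return cls(df, channel)

    def condition_means(self) -> pd.DataFrame:
        """Per-spot mean over replicates of each condition (NaN-propagating)."""
        out = {}
        for cond in self.conditions:
            cols = self.columns_for(cond)
            block = self.data[cols]
            out[cond] = np.where(block.isna().any(axis=1), np.nan,
                                 block.mean(axis=1))
        return pd.DataFrame(out, index=self.data.index)
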