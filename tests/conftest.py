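import numpy as np
import pandas as pd
import pytest

from retroflux.matrix import SpotMatrix, CONDITIONS, sample_name


def build_matrix(values: np.ndarray, channel: str = "autoradiogram",
                 conditions=CONDITIONS, n_replicates: int = 3,
                 spot_ids=None) -> SpotMatrix:
    """Assemble a SpotMatrix from a (spots × conditions*replicates) array."""
    values = np.asarray(values, float)
    cols = [sample_name(c, r, channel)
            for c in conditions for r in range(1, n_replicates + 1)]
    assert values.shape[1] == len(cols)
    if spot_ids is None:
        spot_ids = [f"spot_{i + 1:04d}" for i in range(values.shape[0])]
    return SpotMatrix(pd.DataFrame(values, index=pd.Index(spot_ids, name="spot_id"),
                                   columns=cols), channel)


def foldchange_frame(values: dict, method: str = "de_novo",
                     contrasts=("N→H/N", "L→H/L")) -> pd.DataFrame:
    """Long fold-change table from {feature: (value per contrast, ...)}."""
    rows = [(fid, method, contrast, float(v), False)
            for fid, vals in values.items()
            for contrast, v in zip(contrasts, vals)]
    return pd.DataFrame(rows, columns=["feature_id", "method", "contrast",
                                       "f_poi", "nd"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def clean_experiment():
    """Noise-free experiment with no nuisance processes: exact expectations."""
    from retroflux.simulate import study_config, generate_experiment
    cfg = study_config(seed=5, noise_sd=0.0, discordance_fraction=0.0,
                       nd_dropout_rate=0.0, dominant_spot_share=0.0)
    return generate_experiment(cfg)
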