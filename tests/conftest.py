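import numpy as np
import pandas as pd
import pytest

from relaxsel.simulate import default_config, simulate_dataset


@pytest.fixture(scope="session")
def toy_records() -> pd.DataFrame:
    """Six hand-written records: one (study, trait) group has a single value."""
    return pd.DataFrame(
        {
            "context": ["domestication"] * 6,
            "study_id": ["s1", "s1", "s1", "s1", "s1", "s2"],
            "species_id": ["sp1"] * 5 + ["sp2"],
            "trait_id": ["fid", "fid", "fid", "vig", "vig", "fid"],
            "trait_class": ["behavioral"] * 6,
            "generation": [0.0, 5.0, 10.0, 0.0, 10.0, 3.0],
            "raw_mean": [1.0, 2.0, 3.0, -5.0, -3.0, 4.0],
            "raw_sd": [0.5, 0.5, 0.5, 1.0, 1.0, 2.0],
            "sample_size": [10, 10, 10, 8, 8, 12],
            "direction": [1, 1, 1, -1, -1, 1],
            "selected_for_high_fear": [False] * 6,
        }
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition synthetic dataset, shared across tests."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same structure with every noise source switched off."""
    cfg = default_config(seed=12)
    for cc in cfg.contexts.values():
        cc.sd = {k: 0.0 for k in cc.sd}
        cc.residual_sd = 0.0
        cc.cv_noise_sd = 0.0
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
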