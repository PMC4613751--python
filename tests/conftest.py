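import numpy as np
import pandas as pd
import pytest

from epstscan.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small but fully structured synthetic dataset shared across tests."""
    cfg = SimConfig(
        n_transcripts=400,
        n_per_progeny=16,
        frac_sex_de=0.3,
        frac_progeny_de=0.1,
        frac_additive=0.5,
        missing_rate=0.01,
        bad_feature_rate=0.005,
        seed=123,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def balanced_metadata():
    """Balanced 2x2 metadata: 4 samples per sex x progeny cell."""
    rows = []
    for progeny in ("DAN", "FRA"):
        for sex in ("F", "M"):
            for i in range(4):
                rows.append({"sample_id": f"{progeny}_{sex}{i}", "progeny": progeny, "sex": sex})
    return pd.DataFrame(rows).set_index("sample_id")
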