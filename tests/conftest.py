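import numpy as np
import pandas as pd
import pytest

import faceenc as fe
from faceenc.synthetic import drop_blocks, simulate_features, standard_events

#: Single suite-wide seed for every stochastic check.
SEED = 1


@pytest.fixture(scope="session")
def config() -> fe.PipelineConfig:
    return fe.PipelineConfig(rng_seed=SEED)


@pytest.fixture(scope="session")
def events() -> pd.DataFrame:
    return standard_events()


@pytest.fixture(scope="session")
def features_full(events, config):
    return simulate_features(events, seed=SEED, names=config.feature_names)


@pytest.fixture(scope="session")
def features(features_full):
    return drop_blocks(features_full, (9,))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


def make_channels(names, region="pSTC", status=None):
    n = len(names)
    return pd.DataFrame({
        "name": list(names),
        "region": [region] * n if isinstance(region, str) else list(region),
        "hemisphere": ["L"] * n,
        "status": ["good"] * n if status is None else list(status),
    })


@pytest.fixture
def small_recording(rng):
    channels = make_channels([f"ch{i}" for i in range(4)], region="other")
    data = rng.standard_normal((4096, 4))
    return fe.Recording(data=data, fs=2048.0, channels=channels)
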