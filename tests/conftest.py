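import logging

import numpy as np
import pytest

import mibci

# the pipeline warns once per call about the clipped upper band edge; keep
# test output readable
logging.getLogger("mibci.preprocessing").setLevel(logging.ERROR)
logging.getLogger("mibci.emg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config() -> mibci.SimConfig:
    return mibci.SimConfig(seed=42)


@pytest.fixture(scope="session")
def strong_erd_session():
    """High-SNR lateralized session: deep ERD, low background noise."""
    cfg = mibci.SimConfig(erd_depth=0.8, noise_scale=2.0, artifact_rate=0.0, seed=7)
    rec, truth = mibci.simulate_session(cfg)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def strong_erd_epochs(strong_erd_session):
    rec, _, _ = strong_erd_session
    clean = mibci.preprocess_pipeline(rec)
    return mibci.epoch(clean, 0.0, 10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
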