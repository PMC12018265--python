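import warnings

import numpy as np
import pytest

from thetanav import pipeline
from thetanav.synth import SynthConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """One small structured session shared across test modules."""
    cfg = SynthConfig(rng_seed=42, n_real=10, n_imag=8, n_control=8,
                      seg_length_range=(2.2, 3.0))
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def prepared(small_session):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.prepare_session(small_session, band_max_seconds=40.0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Single-participant, two-channel config for detector tests."""
    return SynthConfig(rng_seed=7, n_channels=2, n_participants=1, n_real=6,
                       n_imag=0, n_control=0, seg_length_range=(2.5, 3.5))
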