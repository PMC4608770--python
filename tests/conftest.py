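"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from painfeat.features import BaselineReference, FeatureConfig
from painfeat.preprocess import preprocess_subject
from painfeat.simulate import SimConfig, generate_schedule, simulate_subject


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Standard protocol, two subjects (smoke scale)."""
    return SimConfig(n_subjects=2, rng_seed=42)


@pytest.fixture(scope="session")
def subject0(small_cfg):
    """One fully simulated subject (recording + schedule)."""
    return simulate_subject(small_cfg, 0)


@pytest.fixture(scope="session")
def preprocessed0(subject0):
    """Subject 0 preprocessed: filtered/EMD windows + RR series."""
    rec, schedule = subject0
    return preprocess_subject(rec, schedule)


@pytest.fixture(scope="session")
def baseline_ref(preprocessed0):
    return BaselineReference.from_windows(preprocessed0.windows)


@pytest.fixture(scope="session")
def feature_cfg():
    return FeatureConfig()


@pytest.fixture(scope="session")
def default_schedule():
    """A standard 80-stimulus schedule (seeded)."""
    cfg = SimConfig(rng_seed=3)
    return generate_schedule(cfg, np.random.default_rng(3))
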